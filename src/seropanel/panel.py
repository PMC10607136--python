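"""Combination-panel classification and ROC analysis.

A panel is a small set of antibodies (e.g. three kinesin fragments)
combined either by a binary k-of-m rule ("positive for at least k of the
panel") or by a continuous score built from nMAD intensities. ROC curves
sweep thresholds at midpoints between adjacent unique scores; the AUC is
the trapezoidal area, which equals the Mann–Whitney probability with
ties counted 1/2. Curve differences are assessed with a paired,
class-stratified bootstrap.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CallMatrix, NMadMatrix

__all__ = [
    "PanelDefinition",
    "RocResult",
    "BootstrapComparison",
    "panel_binary_call",
    "panel_score",
    "roc_curve",
    "mann_whitney_auc",
    "operating_point",
    "bootstrap_compare",
]

INTENSITY_RULES = ("sum_nmad", "max_nmad", "count_positive")


@dataclass(frozen=True)
class PanelDefinition:
    """An ordered antibody panel with its combination rules."""

    antigen_ids: tuple
    k: int = 1
    intensity_rule: str = "sum_nmad"

    def __post_init__(self):
        object.__setattr__(self, "antigen_ids", tuple(self.antigen_ids))
        if not 1 <= self.k <= len(self.antigen_ids):
            raise ValueError("k must satisfy 1 <= k <= panel size")
        if self.intensity_rule not in INTENSITY_RULES:
            raise ValueError(f"intensity_rule must be one of {INTENSITY_RULES}")


def _check_panel_ids(columns, panel: PanelDefinition):
    missing = [a for a in panel.antigen_ids if a not in columns]
    if missing:
        raise KeyError(f"panel antigen id(s) not in matrix: {missing}")


def panel_binary_call(calls: CallMatrix, panel: PanelDefinition) -> pd.Series:
    """Per-sample panel positivity: ≥ k of the panel antibodies called."""
    _check_panel_ids(calls.calls.columns, panel)
    count = calls.calls[list(panel.antigen_ids)].sum(axis=1)
    return (count >= panel.k).rename("panel_positive")


def panel_score(
    nmad: NMadMatrix | None, calls: CallMatrix | None, panel: PanelDefinition
) -> pd.Series:
    """Continuous panel score for ROC analysis.

    ``sum_nmad``/``max_nmad`` need the nMAD matrix (degenerate samples
    yield NaN); ``count_positive`` needs the call matrix and is the
    "binary data" score (0..panel size).
    """
    if panel.intensity_rule == "count_positive":
        if calls is None:
            raise ValueError("count_positive rule needs a CallMatrix")
        _check_panel_ids(calls.calls.columns, panel)
        return calls.calls[list(panel.antigen_ids)].sum(axis=1).astype(float).rename("score")
    if nmad is None:
        raise ValueError(f"{panel.intensity_rule} rule needs an NMadMatrix")
    _check_panel_ids(nmad.scores.columns, panel)
    sub = nmad.scores[list(panel.antigen_ids)]
    if panel.intensity_rule == "sum_nmad":
        out = sub.sum(axis=1, skipna=False)
    else:
        out = sub.max(axis=1, skipna=False)
    return out.rename("score")


@dataclass
class RocResult:
    """A ROC curve: thresholds (descending score), sens/spec arrays, AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_positive: int
    n_negative: int
    bootstrap: "BootstrapComparison | None" = field(default=None)


def _clean_scores(scores, labels):
    scores = pd.Series(scores).astype(float)
    labels = pd.Series(labels)
    if not scores.index.equals(labels.index):
        labels = labels.reindex(scores.index)
    keep = scores.notna() & labels.notna()
    scores, labels = scores[keep], labels[keep].astype(bool)
    if not labels.any() or labels.all():
        raise ValueError("both classes must be present after removing missing scores")
    return scores.to_numpy(), labels.to_numpy()


def roc_curve(scores, labels) -> RocResult:
    """ROC by threshold sweep; classification is ``score > threshold``.

    Thresholds sit at midpoints between adjacent unique scores, with ±inf
    sentinels at the ends. Missing scores are excluded pairwise.
    """
    s, y = _clean_scores(scores, labels)
    unique = np.unique(s)
    mids = (unique[:-1] + unique[1:]) / 2
    thresholds = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = s > t
        sens[i] = (pred & y).sum() / n_pos
        spec[i] = (~pred & ~y).sum() / n_neg
    fpr = 1 - spec
    auc = float(np.trapezoid(sens, fpr))
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def mann_whitney_auc(scores, labels) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + ½·P(tie).

    Independent of the threshold sweep; the two routes must agree.
    """
    s, y = _clean_scores(scores, labels)
    ranks = sps.rankdata(s)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def operating_point(roc: RocResult, criterion: str = "youden", value: float | None = None):
    """Pick an operating point on a ROC curve.

    ``youden`` maximizes sensitivity + specificity − 1 (ties broken
    toward higher specificity); ``fixed_specificity`` returns the best
    sensitivity among points with specificity ≥ ``value``. Returns
    (specificity, sensitivity, threshold).
    """
    if criterion == "youden":
        j = roc.sensitivity + roc.specificity - 1
        # primary key: Youden J; tie-break toward higher specificity
        best = np.lexsort((-roc.specificity, -j))[0]
    elif criterion == "fixed_specificity":
        if value is None:
            raise ValueError("fixed_specificity needs a target value")
        ok = roc.specificity >= value
        if not ok.any():
            raise ValueError(f"specificity {value} is unattainable on this curve")
        idx = np.flatnonzero(ok)
        best = idx[np.argmax(roc.sensitivity[idx])]
    else:
        raise ValueError("criterion must be 'youden' or 'fixed_specificity'")
    return (
        float(roc.specificity[best]),
        float(roc.sensitivity[best]),
        float(roc.thresholds[best]),
    )


@dataclass
class BootstrapComparison:
    auc_1: float
    auc_2: float
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int
    n_redrawn: int = 0


def bootstrap_compare(
    scores_1, scores_2, labels, n_boot: int = 2000, seed: int = 0
) -> BootstrapComparison:
    """Paired bootstrap comparison of two ROC curves on the same samples.

    Samples are resampled with replacement, stratified by class (so every
    resample contains both classes); both scores are evaluated on the same
    resample, making the AUC-difference distribution paired. The two-sided
    p-value is the percentile position of zero in that distribution.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    s1 = pd.Series(scores_1).astype(float)
    s2 = pd.Series(scores_2).astype(float)
    y = pd.Series(labels).astype(bool)
    if not (s1.index.equals(s2.index) and s1.index.equals(y.index)):
        raise ValueError("scores_1, scores_2 and labels must share the same samples")
    keep = s1.notna() & s2.notna()
    s1, s2, y = s1[keep].to_numpy(), s2[keep].to_numpy(), y[keep].to_numpy()
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    auc_1 = mann_whitney_auc(pd.Series(s1), pd.Series(y))
    auc_2 = mann_whitney_auc(pd.Series(s2), pd.Series(y))
    for b in range(n_boot):
        pi = rng.choice(pos, size=len(pos), replace=True)
        ni = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([pi, ni])
        yy = y[idx]
        diffs[b] = mann_whitney_auc(pd.Series(s1[idx]), pd.Series(yy)) - mann_whitney_auc(
            pd.Series(s2[idx]), pd.Series(yy)
        )
    ci_low, ci_high = np.percentile(diffs, [2.5, 97.5])
    p = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    return BootstrapComparison(
        auc_1=float(auc_1),
        auc_2=float(auc_2),
        difference=float(auc_1 - auc_2),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(min(p, 1.0)),
        n_boot=n_boot,
        seed=seed,
    )
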