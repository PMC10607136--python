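"""Cohort-level statistics: prevalence scans, rank tests, PCA batch check.

Conventions
-----------
* Fisher's exact test is two-sided with the point-probability
  ("minimum-likelihood") definition: the p-value sums the hypergeometric
  probabilities of all tables with the observed margins whose point
  probability does not exceed the observed one (relative slack 1e-7 for
  floating ties). This is the mainstream convention (R ``fisher.test``).
* Odds ratios are the unconditional (a·d)/(b·c); when any cell is zero a
  0.5 Haldane correction is applied and flagged.
* Two-group load comparisons use an exact permutation Mann–Whitney test
  for combined n ≤ 20 (valid with ties), otherwise the tie- and
  continuity-corrected normal approximation. More than two groups →
  Kruskal–Wallis.
* Multiple-testing adjustment (Benjamini–Hochberg) is available but off
  by default.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .containers import CallMatrix, NMadMatrix

__all__ = [
    "FisherResult",
    "PrevalenceResult",
    "ComparisonSpec",
    "RankTestResult",
    "PcaResult",
    "fisher_exact_2x2",
    "compare_prevalence",
    "prevalence_frame",
    "rank_test_load",
    "load_covariate_correlation",
    "select_antigens_planar",
    "pca_batch_check",
    "adjust_bh",
]

_FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    haldane_corrected: bool = False


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "two_sided"
) -> FisherResult:
    """Exact test on the 2×2 table [[a, b], [c, d]].

    ``a``/``b`` are positives/negatives in group 1, ``c``/``d`` in group 2.
    The hypergeometric null conditions on both margins.
    """
    counts = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in counts):
        raise ValueError("counts must be nonnegative integers")
    a, b, c, d = (int(x) for x in counts)
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    row1, col1 = a + b, a + c
    dist = sps.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    if alternative == "two_sided":
        p = pmf[pmf <= p_obs * (1 + _FISHER_REL_TOL)].sum()
    elif alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "less":
        p = pmf[support <= a].sum()
    else:
        raise ValueError("alternative must be two_sided, greater or less")
    haldane = 0 in (a, b, c, d)
    if haldane:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    return FisherResult(float(min(p, 1.0)), float(odds), haldane)


@dataclass
class PrevalenceResult:
    """Per-antigen 2×2 seroprevalence comparison between two groups."""

    antigen_id: str
    level_1: str
    level_2: str
    a: int  # positive in group 1
    b: int  # negative in group 1
    c: int  # positive in group 2
    d: int  # negative in group 2
    prevalence_1: float
    prevalence_2: float
    odds_ratio: float
    p_value: float
    haldane_corrected: bool
    passes_gap: bool
    q_value: float | None = None

    @property
    def prevalence_gap(self) -> float:
        """Absolute prevalence difference in percentage units."""
        return abs(self.prevalence_1 - self.prevalence_2) * 100


@dataclass(frozen=True)
class ComparisonSpec:
    """A two-level prevalence comparison over a metadata grouping variable.

    ``min_prevalence_gap`` is in percentage units (10 = ten percentage
    points) and only affects the ``passes_gap`` reporting flag.
    """

    group_by: str
    level_1: str
    level_2: str
    antigens: tuple | None = None
    min_prevalence_gap: float = 10.0
    bh_adjust: bool = False


def _group_masks(metadata: pd.DataFrame, spec: ComparisonSpec, sample_ids):
    if spec.group_by not in metadata.columns:
        raise KeyError(f"unknown grouping variable {spec.group_by!r}")
    grouping = metadata.loc[metadata.index.intersection(sample_ids), spec.group_by]
    g1 = grouping.index[grouping.astype(str) == str(spec.level_1)]
    g2 = grouping.index[grouping.astype(str) == str(spec.level_2)]
    for level, ids in ((spec.level_1, g1), (spec.level_2, g2)):
        if len(ids) == 0:
            raise ValueError(
                f"no samples with {spec.group_by} == {level!r} among the calls"
            )
    return g1, g2


def compare_prevalence(
    calls: CallMatrix, metadata: pd.DataFrame, spec: ComparisonSpec
) -> list[PrevalenceResult]:
    """Fisher prevalence scan of every antigen between two sample groups."""
    g1, g2 = _group_masks(metadata, spec, calls.sample_ids)
    frame = calls.calls
    antigens = list(spec.antigens) if spec.antigens is not None else list(frame.columns)
    missing = [a for a in antigens if a not in frame.columns]
    if missing:
        raise KeyError(f"unknown antigen id(s): {missing}")
    n1, n2 = len(g1), len(g2)
    results = []
    for antigen in antigens:
        a = int(frame.loc[g1, antigen].sum())
        c = int(frame.loc[g2, antigen].sum())
        b, d = n1 - a, n2 - c
        fisher = fisher_exact_2x2(a, b, c, d)
        prev_1, prev_2 = a / n1, c / n2
        results.append(
            PrevalenceResult(
                antigen_id=antigen,
                level_1=str(spec.level_1),
                level_2=str(spec.level_2),
                a=a,
                b=b,
                c=c,
                d=d,
                prevalence_1=prev_1,
                prevalence_2=prev_2,
                odds_ratio=fisher.odds_ratio,
                p_value=fisher.p_value,
                haldane_corrected=fisher.haldane_corrected,
                passes_gap=abs(prev_1 - prev_2) * 100 >= spec.min_prevalence_gap,
            )
        )
    if spec.bh_adjust and results:
        q = adjust_bh([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


def prevalence_frame(results: list[PrevalenceResult]) -> pd.DataFrame:
    """Tabulate a prevalence scan for export."""
    return pd.DataFrame(
        [
            {
                "antigen_id": r.antigen_id,
                "level_1": r.level_1,
                "level_2": r.level_2,
                "pos_1": r.a,
                "neg_1": r.b,
                "pos_2": r.c,
                "neg_2": r.d,
                "prevalence_1": r.prevalence_1,
                "prevalence_2": r.prevalence_2,
                "prevalence_gap_pct": r.prevalence_gap,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "haldane_corrected": r.haldane_corrected,
                "passes_gap": r.passes_gap,
            }
            for r in results
        ]
    )


@dataclass(frozen=True)
class RankTestResult:
    p_value: float
    statistic: float
    test: str  # "mann_whitney_exact", "mann_whitney_normal" or "kruskal_wallis"
    group_medians: dict


_EXACT_RANK_LIMIT = 20


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    u_stat = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    if len(x) + len(y) <= _EXACT_RANK_LIMIT:
        # exact full enumeration of group assignments; valid with ties
        res = sps.permutation_test(
            (x, y),
            lambda a, b, axis=-1: sps.rankdata(
                np.concatenate([a, b], axis=axis), axis=axis
            ).take(range(a.shape[axis]), axis=axis).sum(axis=axis),
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
            vectorized=True,
        )
        return float(res.pvalue), float(u_stat), "mann_whitney_exact"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return float(res.pvalue), float(res.statistic), "mann_whitney_normal"


def rank_test_load(
    loads: pd.Series, metadata: pd.DataFrame, group_by: str, levels=None
) -> RankTestResult:
    """Nonparametric comparison of autoantibody load across groups.

    Two levels → Mann–Whitney–Wilcoxon (exact permutation enumeration for
    combined n ≤ 20, normal approximation with tie/continuity correction
    otherwise); three or more → Kruskal–Wallis. Samples with missing
    grouping values are excluded listwise.
    """
    if group_by not in metadata.columns:
        raise KeyError(f"unknown grouping variable {group_by!r}")
    grouping = metadata.loc[metadata.index.intersection(loads.index), group_by]
    grouping = grouping[grouping.notna() & (grouping.astype(str) != "unknown")]
    if levels is None:
        levels = sorted(grouping.astype(str).unique())
    groups = [
        loads.loc[grouping.index[grouping.astype(str) == str(level)]].to_numpy(float)
        for level in levels
    ]
    groups = [(lvl, g) for lvl, g in zip(levels, groups)]
    empty = [lvl for lvl, g in groups if len(g) == 0]
    if empty:
        raise ValueError(f"empty group level(s): {empty}")
    if len(groups) < 2:
        raise ValueError("need at least two group levels")
    medians = {str(lvl): float(np.median(g)) for lvl, g in groups}
    if len(groups) == 2:
        p, stat, method = _mann_whitney(groups[0][1], groups[1][1])
        return RankTestResult(p, stat, method, medians)
    stat, p = sps.kruskal(*[g for _, g in groups])
    return RankTestResult(float(p), float(stat), "kruskal_wallis", medians)


def load_covariate_correlation(loads: pd.Series, covariate: pd.Series):
    """Spearman correlation between load and a numeric covariate.

    Missing pairs are excluded listwise; at least 3 complete pairs are
    required. Returns (rho, p).
    """
    paired = pd.concat([loads.rename("load"), covariate.rename("cov")], axis=1).dropna()
    if len(paired) < 3:
        raise ValueError("need at least 3 complete (load, covariate) pairs")
    rho, p = sps.spearmanr(paired["load"], paired["cov"])
    return float(rho), float(p)


def select_antigens_planar(calls: CallMatrix, min_positive_samples: int = 2) -> list:
    """Antigens reactive in at least ``min_positive_samples`` samples.

    Mirrors the carry-over rule used to promote antigens from an
    untargeted planar screen into a targeted bead array.
    """
    if min_positive_samples < 1:
        raise ValueError("min_positive_samples must be >= 1")
    counts = calls.calls.sum(axis=0)
    return list(counts.index[counts >= min_positive_samples])


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples × components
    explained_variance_ratio: np.ndarray
    imputed_fraction: float


def pca_batch_check(
    nmad: NMadMatrix, n_components: int = 2
) -> PcaResult:
    """PCA of the nMAD score matrix for batch/diagnosis checks.

    Antigen columns are mean-centered (scikit-learn PCA); missing scores
    from degenerate samples are mean-imputed per antigen first and the
    imputed fraction is reported. ``n_components`` beyond the matrix rank
    is truncated with a warning-free clamp.
    """
    frame = nmad.scores
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 antigens")
    imputed_fraction = float(frame.isna().to_numpy().mean())
    filled = frame.fillna(frame.mean(axis=0)).fillna(0.0)
    k = int(min(n_components, min(filled.shape) - 1, filled.shape[1]))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(filled.to_numpy())
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=frame.index, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        imputed_fraction=imputed_fraction,
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
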