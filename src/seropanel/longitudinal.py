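"""Matched-timepoint comparisons: diagnosis vs remission (vs relapse).

Load differences between matched timepoints are tested with the
two-sided Wilcoxon signed-rank test (zeros dropped); per-antigen
serostatus changes with an exact McNemar binomial test on discordant
pairs. Both are declared nonparametric surrogates — consistent with the
rank-based toolkit used everywhere else in this package.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CallMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedSeries",
    "PairedLoadResult",
    "PairedPositivityResult",
    "build_matched_series",
    "paired_load_test",
    "paired_positivity_test",
]


@dataclass
class MatchedSeries:
    """One subject's samples across timepoints (≥ 2 timepoints)."""

    subject_id: str
    sample_ids: dict  # timepoint -> sample_id
    loads: dict  # timepoint -> int
    calls: dict  # timepoint -> pd.Series (per-antigen 0/1)


def build_matched_series(
    calls: CallMatrix, loads: pd.Series, metadata: pd.DataFrame
) -> list[MatchedSeries]:
    """Group samples by subject; keep subjects with ≥ 2 timepoints."""
    for col in ("subject_id", "timepoint"):
        if col not in metadata.columns:
            raise KeyError(f"metadata missing column {col!r}")
    meta = metadata.loc[metadata.index.intersection(calls.sample_ids)]
    pairs = meta[["subject_id", "timepoint"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        raise ValidationError(
            f"duplicate (subject, timepoint) pair: {pairs[pairs.duplicated()].iloc[0]}"
        )
    series = []
    for subject, rows in meta.groupby("subject_id", sort=True):
        if len(rows) < 2:
            logger.info("subject %s has a single timepoint; excluded", subject)
            continue
        sample_ids = dict(zip(rows["timepoint"], rows.index))
        series.append(
            MatchedSeries(
                subject_id=str(subject),
                sample_ids=sample_ids,
                loads={tp: int(loads.loc[sid]) for tp, sid in sample_ids.items()},
                calls={tp: calls.calls.loc[sid] for tp, sid in sample_ids.items()},
            )
        )
    if not series:
        logger.warning("no subjects with matched timepoints")
    return series


@dataclass(frozen=True)
class PairedLoadResult:
    p_value: float
    median_difference: float
    n_pairs: int
    degenerate: bool  # all within-subject differences were zero


def paired_load_test(
    series: list[MatchedSeries], timepoints: tuple[str, str] = ("diagnosis", "remission")
) -> PairedLoadResult:
    """Wilcoxon signed-rank on within-subject load differences.

    The difference is loads[first] − loads[second]; zero differences are
    dropped per the standard convention, and a cohort where every
    difference is zero is reported as p = 1 with a degenerate flag.
    """
    t1, t2 = timepoints
    diffs = np.array(
        [s.loads[t1] - s.loads[t2] for s in series if t1 in s.loads and t2 in s.loads],
        dtype=float,
    )
    if len(diffs) < 2:
        raise ValueError("need at least 2 complete timepoint pairs")
    if (diffs == 0).all():
        return PairedLoadResult(1.0, 0.0, len(diffs), True)
    res = sps.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided")
    return PairedLoadResult(
        float(res.pvalue), float(np.median(diffs)), len(diffs), False
    )


@dataclass(frozen=True)
class PairedPositivityResult:
    antigen_id: str
    n_pos_to_neg: int
    n_neg_to_pos: int
    n_pairs: int
    p_value: float


def paired_positivity_test(
    series: list[MatchedSeries],
    antigen_id: str,
    timepoints: tuple[str, str] = ("diagnosis", "remission"),
) -> PairedPositivityResult:
    """Exact McNemar test on discordant serostatus pairs for one antigen.

    p is the exact two-sided binomial probability of the observed
    discordant split under H0: switches in either direction are equally
    likely. Concordant pairs never change the p-value; zero discordant
    pairs give p = 1.
    """
    t1, t2 = timepoints
    pairs = [
        (int(s.calls[t1].loc[antigen_id]), int(s.calls[t2].loc[antigen_id]))
        for s in series
        if t1 in s.calls and t2 in s.calls
    ]
    if not pairs:
        raise ValueError("no complete timepoint pairs")
    n10 = sum(1 for x, y in pairs if x == 1 and y == 0)
    n01 = sum(1 for x, y in pairs if x == 0 and y == 1)
    n_disc = n10 + n01
    p = 1.0 if n_disc == 0 else float(sps.binomtest(n10, n_disc, 0.5).pvalue)
    return PairedPositivityResult(
        antigen_id=antigen_id,
        n_pos_to_neg=n10,
        n_neg_to_pos=n01,
        n_pairs=len(pairs),
        p_value=p,
    )
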