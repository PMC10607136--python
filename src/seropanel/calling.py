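"""Per-sample robust seropositivity calling and nMAD normalization.

The calling statistic is computed row-wise (per sample) across all
antigens on the same array. For a sample's intensity vector ``x``:

    cutoff(x) = median(x) + n * MAD(x),        MAD(x) = median(|x - median(x)|)

and a value is called reactive when it strictly exceeds the cutoff (the
comparison and the optional 1.4826 MAD consistency constant are
configurable). The equivalent continuous score is

    nMAD_i = (x_i - median(x)) / MAD(x)

so that, with the consistency constant off, strict-greater calling at
multiplier ``n`` is exactly ``nMAD > n``. Because both statistics are
ratios of location/scale estimates of the same sample vector, calls are
invariant to per-sample rescaling — the raw MFI scale never matters.

The multiplier ``n`` is assay-specific. Published presets: 30 for planar
arrays, 50 for a broad targeted bead array, 20 for a focused (kinesin)
bead array; :func:`select_n_factor` provides a deterministic data-driven
alternative that caps the cohort-wide positivity rate of every antigen.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CallMatrix, IntensityMatrix, NMadMatrix

__all__ = [
    "CutoffSpec",
    "DegenerateSampleError",
    "ASSAY_N_FACTORS",
    "sample_cutoff",
    "call_reactivity",
    "normalize_nmad",
    "select_n_factor",
    "autoantibody_load",
]

#: Published per-assay MAD multipliers: untargeted planar screen, broad
#: targeted bead array, focused kinesin bead array.
ASSAY_N_FACTORS = {"planar": 30.0, "targeted_bead": 50.0, "kinesin_bead": 20.0}

MAD_CONSISTENCY_CONSTANT = 1.4826


class DegenerateSampleError(ValueError):
    """Raised when a sample's MAD is zero and no fallback is allowed."""


@dataclass(frozen=True)
class CutoffSpec:
    """How to turn a sample's intensity vector into a reactivity cutoff.

    Parameters
    ----------
    n_factor
        Positive MAD multiplier (e.g. 50 for a broad targeted bead array).
    mad_consistency
        Multiply the MAD by 1.4826 (the Gaussian consistency constant).
        Off by default: the published formula uses the raw MAD.
    strictness
        "strict_greater" (default) calls only values strictly above the
        cutoff; "greater_equal" also calls ties.
    """

    n_factor: float
    mad_consistency: bool = False
    strictness: str = "strict_greater"

    def __post_init__(self):
        if self.n_factor <= 0:
            raise ValueError("n_factor must be > 0")
        if self.strictness not in ("strict_greater", "greater_equal"):
            raise ValueError("strictness must be strict_greater or greater_equal")


def _median_mad(values: np.ndarray, mad_consistency: bool) -> tuple[np.ndarray, np.ndarray]:
    med = np.median(values, axis=-1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=-1)
    if mad_consistency:
        mad = mad * MAD_CONSISTENCY_CONSTANT
    return np.squeeze(med, axis=-1), mad


def sample_cutoff(intensities, spec: CutoffSpec) -> float:
    """Cutoff for one sample: median + n_factor × MAD of its antigen vector.

    Raises :class:`DegenerateSampleError` when the MAD is zero (e.g. a
    constant vector) — the caller decides the fallback.
    """
    x = np.asarray(intensities, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector of at least 2 intensities")
    if not np.isfinite(x).all():
        raise ValueError("intensities must be finite")
    med, mad = _median_mad(x, spec.mad_consistency)
    if mad == 0:
        raise DegenerateSampleError("sample MAD is zero; cutoff undefined")
    return float(med + spec.n_factor * mad)


def call_reactivity(
    matrix: IntensityMatrix,
    spec: CutoffSpec,
    degenerate_policy: str = "exclude",
) -> CallMatrix:
    """Binary reactive/non-reactive calls with per-sample cutoffs.

    Samples whose MAD is zero are flagged degenerate. Under
    ``degenerate_policy="exclude"`` (default) nothing is called for them
    and their recorded cutoff is the sample maximum; under ``"min_mad"``
    the smallest nonzero MAD in the cohort is substituted.
    """
    if degenerate_policy not in ("exclude", "min_mad"):
        raise ValueError("degenerate_policy must be 'exclude' or 'min_mad'")
    values = matrix.values
    med, mad = _median_mad(values, spec.mad_consistency)
    degenerate = mad == 0
    effective_mad = mad.copy()
    if degenerate.any():
        if degenerate_policy == "min_mad" and (~degenerate).any():
            effective_mad[degenerate] = mad[~degenerate].min()
        else:
            # nothing can be called for these samples
            effective_mad[degenerate] = np.inf
    cutoffs = med + spec.n_factor * effective_mad
    if spec.strictness == "strict_greater":
        calls = values > cutoffs[:, None]
    else:
        calls = values >= cutoffs[:, None]
    finite_cutoffs = np.where(
        np.isfinite(cutoffs), cutoffs, values.max(axis=1)
    )
    return CallMatrix(
        calls=pd.DataFrame(
            calls.astype(np.int8), index=matrix.data.index, columns=matrix.data.columns
        ),
        cutoffs=pd.Series(finite_cutoffs, index=matrix.data.index, name="cutoff"),
        n_factor=spec.n_factor,
        degenerate=[s for s, d in zip(matrix.sample_ids, degenerate) if d],
    )


def normalize_nmad(matrix: IntensityMatrix, mad_consistency: bool = False) -> NMadMatrix:
    """Robust per-sample z-like scores: (value − median) / MAD, row-wise.

    Degenerate samples (MAD = 0) get NaN scores and are listed in the
    result's ``degenerate`` attribute.
    """
    values = matrix.values
    med, mad = _median_mad(values, mad_consistency)
    degenerate = mad == 0
    safe_mad = np.where(degenerate, np.nan, mad)
    scores = (values - med[:, None]) / safe_mad[:, None]
    return NMadMatrix(
        scores=pd.DataFrame(scores, index=matrix.data.index, columns=matrix.data.columns),
        medians=pd.Series(med, index=matrix.data.index, name="median"),
        mads=pd.Series(mad, index=matrix.data.index, name="mad"),
        degenerate=[s for s, d in zip(matrix.sample_ids, degenerate) if d],
    )


def select_n_factor(
    matrix: IntensityMatrix,
    candidates,
    target_max_prevalence: float,
    mad_consistency: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Smallest multiplier capping every antigen's cohort positivity rate.

    Scans ``candidates`` (ascending) and returns the first for which no
    antigen is called positive in more than ``target_max_prevalence`` of
    samples, together with a per-candidate diagnostic table. If no
    candidate qualifies the largest is returned with a warning in the
    table's ``satisfied`` column.
    """
    candidates = sorted(float(c) for c in candidates)
    if not candidates:
        raise ValueError("candidates must be nonempty")
    if not 0 < target_max_prevalence <= 1:
        raise ValueError("target_max_prevalence must be in (0, 1]")
    rows = []
    chosen = None
    for n in candidates:
        calls = call_reactivity(
            matrix, CutoffSpec(n_factor=n, mad_consistency=mad_consistency)
        )
        rates = calls.calls.mean(axis=0)
        ok = rates.max() <= target_max_prevalence
        rows.append(
            {
                "n_factor": n,
                "max_antigen_prevalence": float(rates.max()),
                "mean_antigen_prevalence": float(rates.mean()),
                "n_antigens_above_target": int((rates > target_max_prevalence).sum()),
                "satisfied": bool(ok),
            }
        )
        if ok and chosen is None:
            chosen = n
    table = pd.DataFrame(rows)
    if chosen is None:
        chosen = candidates[-1]
    return chosen, table


def autoantibody_load(calls: CallMatrix, antigen_subset=None) -> pd.Series:
    """Per-sample count of positive calls (over an optional antigen subset)."""
    frame = calls.calls
    if antigen_subset is not None:
        missing = [a for a in antigen_subset if a not in frame.columns]
        if missing:
            raise KeyError(f"unknown antigen id(s): {missing}")
        frame = frame[list(antigen_subset)]
    return frame.sum(axis=1).rename("load")
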