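"""ELISA verification: healthy-control-based cutoff and positivity calls.

The ELISA readout is optical density at 450 nm (OD450). The positivity
cutoff is mean + 3·SD of the healthy-control ODs (sample SD, n−1
denominator); a test sample is positive when its OD strictly exceeds the
cutoff. Control wells are never themselves called.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CallMatrix, ValidationError
from .stats import FisherResult, fisher_exact_2x2

__all__ = ["ElisaPlate", "ElisaCalls", "ConcordanceResult", "elisa_cutoff", "elisa_call",
           "cross_platform_concordance", "read_elisa_plate"]


@dataclass
class ElisaPlate:
    """OD450 readings for one antigen: per-sample values + control flags."""

    od450: pd.Series  # indexed by sample_id
    is_control: pd.Series  # bool, same index
    antigen_label: str = ""

    def __post_init__(self):
        if not self.od450.index.equals(self.is_control.index):
            raise ValidationError("od450 and is_control must share sample ids")
        values = self.od450.to_numpy(float)
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValidationError("OD450 values must be finite and >= 0")
        if int(self.is_control.sum()) < 2:
            raise ValidationError("need at least 2 healthy-control wells for a cutoff")


def elisa_cutoff(control_ods) -> float:
    """mean + 3 × sample SD (n−1) of the healthy-control ODs."""
    x = np.asarray(control_ods, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 control OD values")
    return float(x.mean() + 3 * x.std(ddof=1))


@dataclass
class ElisaCalls:
    positive: pd.Series  # bool per test sample
    cutoff: float
    antigen_label: str = ""


def elisa_call(plate: ElisaPlate) -> ElisaCalls:
    """Binary positivity per test sample: OD strictly above the cutoff."""
    cutoff = elisa_cutoff(plate.od450[plate.is_control])
    test = plate.od450[~plate.is_control]
    return ElisaCalls(
        positive=(test > cutoff).rename("elisa_positive"),
        cutoff=cutoff,
        antigen_label=plate.antigen_label,
    )


@dataclass
class ConcordanceResult:
    """2×2 agreement between bead-array and ELISA calls for one antigen."""

    table: pd.DataFrame  # rows bead +/-, columns elisa +/-
    agreement: float
    fisher: FisherResult
    n_overlap: int


def cross_platform_concordance(
    bead_calls: CallMatrix, elisa_calls: pd.Series, antigen_id: str
) -> ConcordanceResult:
    """Agreement of bead-array and ELISA positivity on overlapping samples."""
    if antigen_id not in bead_calls.calls.columns:
        raise KeyError(f"unknown antigen id {antigen_id!r}")
    bead = bead_calls.calls[antigen_id].astype(bool)
    overlap = bead.index.intersection(elisa_calls.index)
    if len(overlap) == 0:
        raise ValueError("no overlapping sample ids between platforms")
    bead = bead.loc[overlap]
    elisa = elisa_calls.loc[overlap].astype(bool)
    a = int((bead & elisa).sum())
    b = int((bead & ~elisa).sum())
    c = int((~bead & elisa).sum())
    d = int((~bead & ~elisa).sum())
    table = pd.DataFrame(
        [[a, b], [c, d]],
        index=pd.Index(["bead_pos", "bead_neg"]),
        columns=pd.Index(["elisa_pos", "elisa_neg"]),
    )
    return ConcordanceResult(
        table=table,
        agreement=(a + d) / len(overlap),
        fisher=fisher_exact_2x2(a, b, c, d),
        n_overlap=len(overlap),
    )


def read_elisa_plate(path, antigen_label: str = "") -> ElisaPlate:
    """Read a plate TSV/CSV with columns sample_id, od450, is_control."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep)
    required = ("sample_id", "od450", "is_control")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"ELISA plate missing column(s): {missing}")
    frame = frame.set_index("sample_id")
    is_control = frame["is_control"].astype(str).str.strip().str.lower().isin(
        ("1", "true", "yes")
    )
    return ElisaPlate(
        od450=frame["od450"].astype(float),
        is_control=is_control,
        antigen_label=antigen_label,
    )
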