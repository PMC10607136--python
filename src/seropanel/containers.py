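"""Core in-memory containers for bead-array serology data.

All matrices are pandas-backed with samples in rows and antigens in
columns; sample and antigen identifiers live on the index/columns and are
required to be unique. Raw intensities are median fluorescence intensity
(MFI) in arbitrary units; calls are 0/1; nMAD scores are unitless robust
deviations from the per-sample median.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "CallMatrix",
    "NMadMatrix",
    "SampleRecord",
    "AntigenRecord",
    "ValidationError",
    "GROUPS",
    "SITES",
    "TIMEPOINTS",
    "ANCA_SEROTYPES",
    "PHENOTYPES",
    "SEXES",
    "ORGANS",
]

GROUPS = ("AAV", "GCA", "PMR", "HC")
SITES = ("MUW", "UCAM", "UMCG", "SYNTH")
TIMEPOINTS = ("diagnosis", "remission", "relapse", "single")
ANCA_SEROTYPES = ("MPO", "PR3", "negative", "unknown")
PHENOTYPES = ("MPA", "GPA", "not_applicable", "unknown")
SEXES = ("M", "F", "unknown")
ORGANS = ("kidney", "ENT", "respiratory")


class ValidationError(ValueError):
    """Raised when a container or input file violates its invariants."""


def _check_unique(ids, axis_name: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValidationError(f"duplicate {axis_name} id(s): {list(dups.index[:5])}")


@dataclass
class IntensityMatrix:
    """Raw MFI values for samples (rows) × antigens (columns).

    Values must be finite and non-negative; both axes must carry unique
    identifiers. ``data`` is stored as float64.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(np.float64)
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "antigen")
        values = self.data.to_numpy()
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            s, a = np.argwhere(bad)[0]
            raise ValidationError(
                "non-finite or negative intensity at sample "
                f"{self.data.index[s]!r}, antigen {self.data.columns[a]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def antigen_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "IntensityMatrix":
        return IntensityMatrix(self.data.loc[list(sample_ids)])


@dataclass
class CallMatrix:
    """Binary reactive/non-reactive calls with per-sample cutoffs.

    ``calls`` holds 0/1 integers; ``cutoffs`` is a per-sample Series in raw
    MFI units; ``n_factor`` is the MAD multiplier used; ``degenerate``
    lists sample ids whose MAD was zero (their handling is recorded by the
    calling routine).
    """

    calls: pd.DataFrame
    cutoffs: pd.Series
    n_factor: float
    degenerate: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_factor <= 0:
            raise ValidationError("n_factor must be > 0")
        self.calls = self.calls.astype(np.int8)
        if not self.calls.isin([0, 1]).all().all():
            raise ValidationError("calls must be 0/1")
        if not self.calls.index.equals(self.cutoffs.index):
            raise ValidationError("cutoffs index must match call matrix samples")
        if not np.isfinite(self.cutoffs.to_numpy()).all():
            raise ValidationError("cutoffs must be finite")

    @property
    def sample_ids(self) -> list:
        return list(self.calls.index)

    @property
    def antigen_ids(self) -> list:
        return list(self.calls.columns)


@dataclass
class NMadMatrix:
    """Per-value normalized deviations (value − sample median) / sample MAD.

    Degenerate samples (MAD = 0) carry NaN scores and are listed in
    ``degenerate``. The per-sample medians and MADs used are retained.
    """

    scores: pd.DataFrame
    medians: pd.Series
    mads: pd.Series
    degenerate: list = field(default_factory=list)

    @property
    def sample_ids(self) -> list:
        return list(self.scores.index)

    @property
    def antigen_ids(self) -> list:
        return list(self.scores.columns)


@dataclass
class SampleRecord:
    """One serum sample with its clinical annotations.

    Non-AAV samples are single-timepoint and have no MPA/GPA phenotype.
    Missing clinical values are explicit (``None`` or ``"unknown"``), never
    silently dropped.
    """

    sample_id: str
    subject_id: str
    group: str
    site: str = "SYNTH"
    timepoint: str = "single"
    anca_serotype: str = "unknown"
    phenotype: str = "unknown"
    sex: str = "unknown"
    age: float | None = None
    on_treatment: bool | None = None
    bvas: int | None = None
    organ_involvement: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; allowed: {GROUPS}"
            )
        for name, value, allowed in (
            ("site", self.site, SITES),
            ("timepoint", self.timepoint, TIMEPOINTS),
            ("anca_serotype", self.anca_serotype, ANCA_SEROTYPES),
            ("phenotype", self.phenotype, PHENOTYPES),
            ("sex", self.sex, SEXES),
        ):
            if value not in allowed:
                raise ValidationError(
                    f"invalid {name} {value!r} for sample {self.sample_id!r};"
                    f" allowed: {allowed}"
                )
        if self.group != "AAV":
            if self.timepoint != "single":
                raise ValidationError(
                    f"non-AAV sample {self.sample_id!r} must have timepoint 'single'"
                )
            if self.phenotype not in ("not_applicable",):
                raise ValidationError(
                    f"non-AAV sample {self.sample_id!r} must have phenotype"
                    " 'not_applicable'"
                )
        if self.bvas is not None and self.bvas < 0:
            raise ValidationError("bvas must be non-negative")
        self.organ_involvement = frozenset(self.organ_involvement)
        bad_organs = self.organ_involvement - set(ORGANS)
        if bad_organs:
            raise ValidationError(f"unknown organ flag(s): {sorted(bad_organs)}")


@dataclass
class AntigenRecord:
    """One protein-fragment antigen (gene, UniProt id, fragment span)."""

    antigen_id: str
    gene_symbol: str
    uniprot_id: str
    aa_start: int
    aa_end: int
    family_tag: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValidationError(
                f"antigen {self.antigen_id!r}: need 1 <= aa_start <= aa_end"
            )
        length = self.aa_end - self.aa_start + 1
        if not 40 <= length <= 100:
            warnings.warn(
                f"antigen {self.antigen_id!r} fragment length {length} outside"
                " the typical 40-100 aa range",
                stacklevel=2,
            )

    @property
    def fragment_length(self) -> int:
        return self.aa_end - self.aa_start + 1


def samples_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Tabulate SampleRecords as a DataFrame indexed by sample_id.

    Organ involvement is expanded into boolean ``organ_<name>`` columns so
    group statistics can select on individual flags.
    """
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "subject_id": r.subject_id,
            "group": r.group,
            "site": r.site,
            "timepoint": r.timepoint,
            "anca_serotype": r.anca_serotype,
            "phenotype": r.phenotype,
            "sex": r.sex,
            "age": r.age,
            "on_treatment": r.on_treatment,
            "bvas": r.bvas,
        }
        for organ in ORGANS:
            row[f"organ_{organ}"] = organ in r.organ_involvement
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("sample_id")
    _check_unique(frame.index, "sample")
    pairs = frame[["subject_id", "timepoint"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        dup = pairs[pairs.duplicated()].iloc[0]
        raise ValidationError(f"duplicate (subject, timepoint) pair: {dup}")
    return frame


def antigens_to_frame(records: list[AntigenRecord]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "antigen_id": r.antigen_id,
                "gene_symbol": r.gene_symbol,
                "uniprot_id": r.uniprot_id,
                "aa_start": r.aa_start,
                "aa_end": r.aa_end,
                "family_tag": r.family_tag,
            }
            for r in records
        ]
    ).set_index("antigen_id")
    _check_unique(frame.index, "antigen")
    return frame
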