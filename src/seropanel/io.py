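"""Reading and writing of intensity matrices, metadata and annotation.

File dialects: CSV or TSV (chosen by extension, ``.tsv``/``.txt`` →
tab). Intensity matrices default to samples-in-rows with the header row
carrying antigen ids and the first column carrying sample ids; the
transposed dialect is accepted via ``orientation="antigens_in_rows"``.
"""
from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .containers import (
    ANCA_SEROTYPES,
    GROUPS,
    ORGANS,
    PHENOTYPES,
    SEXES,
    SITES,
    TIMEPOINTS,
    AntigenRecord,
    IntensityMatrix,
    SampleRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

ORIENTATIONS = ("samples_in_rows", "antigens_in_rows")


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_intensity_matrix(path, orientation: str = "samples_in_rows") -> IntensityMatrix:
    """Read a raw MFI matrix from CSV/TSV.

    Raises :class:`ValidationError` on duplicate ids, non-numeric cells and
    negative or non-finite values, naming the offending coordinate.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "antigens_in_rows":
        frame = frame.T
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna() | frame[col].isna()
        if bad.any():
            row = frame.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"non-numeric or missing intensity at sample {row!r}, antigen {col!r}"
            )
        frame[col] = coerced
    return IntensityMatrix(frame)


def write_intensity_matrix(matrix: IntensityMatrix, path) -> None:
    matrix.data.to_csv(path, sep=_sep_for(path), index_label="sample_id")


_REQUIRED_METADATA_COLUMNS = ("sample_id", "subject_id", "group")


def _coerce_enum(value, allowed, fallback: str, column: str, sample_id: str):
    value = "" if pd.isna(value) else str(value)
    if value in allowed:
        return value
    if value not in ("", "NA", "nan"):
        logger.warning(
            "sample %s: unknown %s %r mapped to %r", sample_id, column, value, fallback
        )
    return fallback


def read_sample_metadata(path) -> list[SampleRecord]:
    """Read sample metadata into validated records.

    ``group`` values outside the known cohort labels are an error (they
    change the analysis); other unknown categories degrade to "unknown"
    with a logged warning. Organ involvement is read from boolean
    ``organ_kidney``/``organ_ENT``/``organ_respiratory`` columns when
    present.
    """
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing = [c for c in _REQUIRED_METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"metadata missing required column(s): {missing}")
    records = []
    for _, row in frame.iterrows():
        sid = row["sample_id"]
        group = row["group"]
        if group not in GROUPS:
            raise ValidationError(
                f"sample {sid!r}: unknown group {group!r}; allowed: {GROUPS}"
            )
        organs = {
            organ
            for organ in ORGANS
            if str(row.get(f"organ_{organ}", "")).strip().lower() in ("1", "true", "yes")
        }

        def _opt_float(key):
            raw = row.get(key)
            return None if raw is None or pd.isna(raw) or raw == "" else float(raw)

        raw_treat = str(row.get("on_treatment", "")).strip().lower()
        on_treatment = (
            None if raw_treat in ("", "na", "nan", "none") else raw_treat in ("1", "true", "yes")
        )
        bvas = _opt_float("bvas")
        records.append(
            SampleRecord(
                sample_id=sid,
                subject_id=row["subject_id"],
                group=group,
                site=_coerce_enum(row.get("site"), SITES, "SYNTH", "site", sid),
                timepoint=_coerce_enum(
                    row.get("timepoint"), TIMEPOINTS, "single", "timepoint", sid
                ),
                anca_serotype=_coerce_enum(
                    row.get("anca_serotype"), ANCA_SEROTYPES, "unknown", "anca_serotype", sid
                ),
                phenotype=_coerce_enum(
                    row.get("phenotype"),
                    PHENOTYPES,
                    "not_applicable" if group != "AAV" else "unknown",
                    "phenotype",
                    sid,
                ),
                sex=_coerce_enum(row.get("sex"), SEXES, "unknown", "sex", sid),
                age=_opt_float("age"),
                on_treatment=on_treatment,
                bvas=None if bvas is None else int(bvas),
                organ_involvement=frozenset(organs),
            )
        )
    return records


def write_sample_metadata(records: list[SampleRecord], path) -> None:
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
            "age": "" if r.age is None else r.age,
            "on_treatment": "" if r.on_treatment is None else r.on_treatment,
            "bvas": "" if r.bvas is None else r.bvas,
        }
        for organ in ORGANS:
            row[f"organ_{organ}"] = organ in r.organ_involvement
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_antigen_annotation(path) -> list[AntigenRecord]:
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = ("antigen_id", "gene_symbol", "uniprot_id", "aa_start", "aa_end")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"annotation missing required column(s): {missing}")
    return [
        AntigenRecord(
            antigen_id=row["antigen_id"],
            gene_symbol=row["gene_symbol"],
            uniprot_id=row["uniprot_id"],
            aa_start=int(row["aa_start"]),
            aa_end=int(row["aa_end"]),
            family_tag=row.get("family_tag", "") or "",
        )
        for _, row in frame.iterrows()
    ]


def write_antigen_annotation(records: list[AntigenRecord], path) -> None:
    pd.DataFrame(
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
    ).to_csv(path, sep=_sep_for(path), index=False)


def qc_filter(
    matrix: IntensityMatrix, min_valid_fraction: float = 0.9
) -> tuple[IntensityMatrix, list[dict]]:
    """Drop samples with too few valid (finite, > 0) antigen measurements.

    Returns the filtered matrix and an exclusion report, one dict per
    excluded sample with its valid fraction. Idempotent. Raises
    :class:`ValidationError` if every sample would be excluded.
    """
    if not 0 < min_valid_fraction <= 1:
        raise ValueError("min_valid_fraction must be in (0, 1]")
    values = matrix.values
    valid_fraction = (np.isfinite(values) & (values > 0)).mean(axis=1)
    keep = valid_fraction >= min_valid_fraction
    report = [
        {
            "sample_id": sid,
            "valid_fraction": float(frac),
            "reason": f"valid antigen fraction {frac:.3f} < {min_valid_fraction}",
        }
        for sid, frac, ok in zip(matrix.sample_ids, valid_fraction, keep)
        if not ok
    ]
    if not keep.any():
        raise ValidationError("qc_filter would exclude every sample")
    for entry in report:
        logger.warning("excluding sample %s: %s", entry["sample_id"], entry["reason"])
    return IntensityMatrix(matrix.data.loc[keep]), report


def write_exclusion_report(report: list[dict], path) -> None:
    with open(path, "w") as handle:
        for entry in report:
            handle.write(json.dumps(entry) + "\n")


def write_call_matrix(calls, path) -> None:
    calls.calls.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def write_nmad_matrix(nmad, path) -> None:
    nmad.scores.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def write_cutoff_table(calls, path) -> None:
    table = pd.DataFrame(
        {
            "cutoff": calls.cutoffs,
            "degenerate": [s in set(calls.degenerate) for s in calls.sample_ids],
        }
    )
    table.to_csv(path, sep=_sep_for(path), index_label="sample_id")
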