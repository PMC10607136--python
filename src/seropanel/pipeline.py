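"""End-to-end orchestration: simulate/ingest → QC → call → statistics → report.

Every run writes its resolved configuration next to its outputs, so a
report directory is self-describing and byte-identical given the same
config and seed. Reports are plain TSV/JSON views of the exported call
and score matrices — every count in them can be re-derived from the
exported matrices.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as spio
from .calling import CutoffSpec, autoantibody_load, call_reactivity, normalize_nmad, select_n_factor
from .containers import samples_to_frame
from .longitudinal import build_matched_series, paired_load_test, paired_positivity_test
from .panel import (
    PanelDefinition,
    bootstrap_compare,
    panel_binary_call,
    panel_score,
    roc_curve,
)
from .simulate import generate_cohort, phase_config
from .stats import ComparisonSpec, compare_prevalence, prevalence_frame

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "export_report_tables"]


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    # input: either a simulation phase or file paths
    phase: str | None = "phase2"
    intensity_path: str | None = None
    metadata_path: str | None = None
    orientation: str = "samples_in_rows"
    # QC and calling
    min_valid_fraction: float = 0.9
    n_factor: float | None = 50.0
    select_n_candidates: tuple = ()
    select_n_max_prevalence: float = 0.5
    mad_consistency: bool = False
    # analyses
    comparisons: tuple = ()  # of dicts: {group_by, level_1, level_2, ...}
    panels: tuple = ()  # of dicts: {antigen_ids, k, intensity_rule, group_by, level_1, level_2}
    bootstrap_n: int = 0
    longitudinal_timepoints: tuple = ("diagnosis", "remission")
    log_level: str = "INFO"

    def to_file(self, path) -> None:
        payload = dataclasses.asdict(self)
        text = (
            yaml.safe_dump(payload, sort_keys=False)
            if str(path).endswith((".yaml", ".yml"))
            else json.dumps(payload, indent=2)
        )
        Path(path).write_text(text)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        payload = (
            yaml.safe_load(text)
            if str(path).endswith((".yaml", ".yml"))
            else json.loads(text)
        )
        for key in ("select_n_candidates", "comparisons", "panels", "longitudinal_timepoints"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run."""

    config: RunConfig
    matrix: object
    metadata: pd.DataFrame
    calls: object
    nmad: object
    loads: pd.Series
    exclusions: list
    truth: object | None = None
    prevalence: dict = field(default_factory=dict)
    panels: dict = field(default_factory=dict)
    longitudinal: dict = field(default_factory=dict)
    chosen_n_factor: float | None = None


def _ingest(config: RunConfig):
    if config.phase is not None:
        sim = phase_config(config.phase, seed=config.seed)
        matrix, samples, antigens, truth = generate_cohort(sim)
        return matrix, samples_to_frame(samples), truth
    if not config.intensity_path or not config.metadata_path:
        raise ValueError("need either a simulation phase or intensity+metadata paths")
    matrix = spio.read_intensity_matrix(config.intensity_path, config.orientation)
    metadata = samples_to_frame(spio.read_sample_metadata(config.metadata_path))
    return matrix, metadata, None


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle to out_dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix, metadata, truth = _ingest(config)
    matrix, exclusions = spio.qc_filter(matrix, config.min_valid_fraction)
    metadata = metadata.loc[metadata.index.intersection(matrix.sample_ids)]

    chosen_n = config.n_factor
    if chosen_n is None:
        if not config.select_n_candidates:
            raise ValueError("set n_factor or select_n_candidates")
        chosen_n, table = select_n_factor(
            matrix,
            config.select_n_candidates,
            config.select_n_max_prevalence,
            config.mad_consistency,
        )
        table.to_csv(out / "n_factor_selection.tsv", sep="\t", index=False)
    spec = CutoffSpec(n_factor=chosen_n, mad_consistency=config.mad_consistency)
    calls = call_reactivity(matrix, spec)
    nmad = normalize_nmad(matrix, config.mad_consistency)
    loads = autoantibody_load(calls)

    bundle = ReportBundle(
        config=config,
        matrix=matrix,
        metadata=metadata,
        calls=calls,
        nmad=nmad,
        loads=loads,
        exclusions=exclusions,
        truth=truth,
        chosen_n_factor=chosen_n,
    )

    for comparison in config.comparisons:
        comparison = dict(comparison)
        name = comparison.pop("name", None) or "{group_by}_{level_1}_vs_{level_2}".format(
            **comparison
        )
        spec_kwargs = {
            k: comparison[k]
            for k in ("group_by", "level_1", "level_2", "min_prevalence_gap", "bh_adjust")
            if k in comparison
        }
        try:
            results = compare_prevalence(calls, metadata, ComparisonSpec(**spec_kwargs))
        except KeyError as exc:
            raise ValueError(f"comparison {name!r} failed: {exc}") from exc
        bundle.prevalence[name] = results

    for panel_cfg in config.panels:
        panel_cfg = dict(panel_cfg)
        name = panel_cfg.pop("name", None) or "panel_" + "_".join(panel_cfg["antigen_ids"])
        panel = PanelDefinition(
            antigen_ids=tuple(panel_cfg["antigen_ids"]),
            k=int(panel_cfg.get("k", 1)),
            intensity_rule=panel_cfg.get("intensity_rule", "sum_nmad"),
        )
        group_by = panel_cfg.get("group_by", "group")
        level_1, level_2 = panel_cfg.get("level_1", "AAV"), panel_cfg.get("level_2", "HC")
        if group_by not in metadata.columns:
            raise ValueError(f"panel {name!r}: unknown grouping variable {group_by!r}")
        grouping = metadata[group_by].astype(str)
        mask = grouping.isin([str(level_1), str(level_2)])
        sample_ids = metadata.index[mask]
        labels = (grouping.loc[sample_ids] == str(level_1)).rename("label")
        binary = panel_binary_call(calls, panel).loc[sample_ids]
        score = panel_score(nmad, calls, panel).loc[sample_ids]
        roc = roc_curve(score, labels)
        entry = {
            "panel": panel,
            "binary_positive": binary,
            "score": score,
            "labels": labels,
            "roc": roc,
            "binary_roc": roc_curve(
                panel_score(None, calls, PanelDefinition(panel.antigen_ids, panel.k, "count_positive")).loc[sample_ids],
                labels,
            ),
        }
        if config.bootstrap_n:
            entry["bootstrap"] = bootstrap_compare(
                score,
                panel_score(
                    None, calls, PanelDefinition(panel.antigen_ids, panel.k, "count_positive")
                ).loc[sample_ids],
                labels,
                n_boot=config.bootstrap_n,
                seed=config.seed,
            )
        bundle.panels[name] = entry

    if "timepoint" in metadata.columns and (metadata["timepoint"] == "remission").any():
        series = build_matched_series(calls, loads, metadata)
        if len(series) >= 2:
            t1, t2 = config.longitudinal_timepoints
            load_res = paired_load_test(series, (t1, t2))
            per_antigen = [
                paired_positivity_test(series, antigen, (t1, t2))
                for antigen in calls.antigen_ids
            ]
            bundle.longitudinal = {
                "n_series": len(series),
                "load_test": load_res,
                "positivity_tests": per_antigen,
            }

    export_report_tables(bundle, out)
    config.to_file(out / "run_config.json")
    return bundle


def export_report_tables(bundle: ReportBundle, out_dir) -> None:
    """Write plot-ready TSV/JSON tables for a completed bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.write_intensity_matrix(bundle.matrix, out / "intensity.tsv")
    spio.write_call_matrix(bundle.calls, out / "calls.tsv")
    spio.write_nmad_matrix(bundle.nmad, out / "nmad.tsv")
    spio.write_cutoff_table(bundle.calls, out / "cutoffs.tsv")
    spio.write_exclusion_report(bundle.exclusions, out / "exclusions.jsonl")
    bundle.metadata.to_csv(out / "metadata.tsv", sep="\t")
    bundle.loads.to_frame().to_csv(out / "loads.tsv", sep="\t", index_label="sample_id")
    if bundle.truth is not None:
        bundle.truth.positivity.to_csv(out / "truth.tsv", sep="\t", index_label="sample_id")

    summary = {
        "n_samples": len(bundle.matrix.sample_ids),
        "n_antigens": len(bundle.matrix.antigen_ids),
        "n_excluded": len(bundle.exclusions),
        "n_factor": bundle.chosen_n_factor,
        "mad_consistency": bundle.config.mad_consistency,
        "min_valid_fraction": bundle.config.min_valid_fraction,
        "seed": bundle.config.seed,
        "median_load": float(bundle.loads.median()),
        "load_range": [int(bundle.loads.min()), int(bundle.loads.max())],
        "degenerate_samples": list(bundle.calls.degenerate),
    }
    for name, results in bundle.prevalence.items():
        prevalence_frame(results).to_csv(out / f"prevalence_{name}.tsv", sep="\t", index=False)
    for name, entry in bundle.panels.items():
        roc = entry["roc"]
        pd.DataFrame(
            {
                "threshold": roc.thresholds,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
            }
        ).to_csv(out / f"roc_{name}.tsv", sep="\t", index=False)
        # heatmap inputs: binary calls and nMAD scores restricted to the panel
        panel_ids = list(entry["panel"].antigen_ids)
        bundle.calls.calls[panel_ids].to_csv(
            out / f"heatmap_binary_{name}.tsv", sep="\t", index_label="sample_id"
        )
        bundle.nmad.scores[panel_ids].to_csv(
            out / f"heatmap_nmad_{name}.tsv", sep="\t", index_label="sample_id"
        )
        panel_summary = {
            "auc_intensity": roc.auc,
            "auc_binary": entry["binary_roc"].auc,
            "n_positive": roc.n_positive,
            "n_negative": roc.n_negative,
            "panel_positive_rate_level1": float(
                entry["binary_positive"][entry["labels"]].mean()
            ),
            "panel_positive_rate_level2": float(
                entry["binary_positive"][~entry["labels"]].mean()
            ),
        }
        if "bootstrap" in entry:
            boot = entry["bootstrap"]
            panel_summary["bootstrap"] = {
                "difference": boot.difference,
                "ci": [boot.ci_low, boot.ci_high],
                "p_value": boot.p_value,
                "n_boot": boot.n_boot,
            }
        summary.setdefault("panels", {})[name] = panel_summary
    if bundle.longitudinal:
        load_res = bundle.longitudinal["load_test"]
        summary["longitudinal"] = {
            "n_series": bundle.longitudinal["n_series"],
            "load_p": load_res.p_value,
            "load_median_difference": load_res.median_difference,
        }
        pd.DataFrame(
            [
                {
                    "antigen_id": r.antigen_id,
                    "pos_to_neg": r.n_pos_to_neg,
                    "neg_to_pos": r.n_neg_to_pos,
                    "n_pairs": r.n_pairs,
                    "p_value": r.p_value,
                }
                for r in bundle.longitudinal["positivity_tests"]
            ]
        ).to_csv(out / "longitudinal_positivity.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
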