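"""Synthetic bead-array serology cohorts with planted seropositivity.

The generator emulates the structure of a multi-site autoantibody
bead-array study: positive, right-skewed (lognormal) antigen backgrounds,
per-sample multiplicative intensity scales, mild multiplicative site
(batch) effects, and a sparse planted set of strongly elevated
"seropositive" values whose per-(group, antigen) probabilities are the
ground truth against which calling is evaluated. Matched longitudinal
samples (diagnosis → remission → relapse) share a subject id; planted
positivity persists from diagnosis to remission with a configurable
probability and relapse reuses the diagnosis truth.

Intensity model for sample s (site b) and antigen a::

    MFI[s, a] = scale_s * site_b * baseline_a * boost[s, a]^truth[s, a] * noise

with every factor lognormal. The raw intensity scale is arbitrary (real
MFI units are instrument-specific); the calling statistic is scale
invariant, so only the ratios matter.

Two ready-made designs are provided by :func:`phase_config`:

* ``phase2`` — a broad targeted array: 126 AAV + 168 HC samples × 151
  antigens, with two antigens planted at modestly elevated AAV
  prevalence (a rare highly specific hit and a common weakly enriched
  one).
* ``phase3`` — a focused kinesin-family array: 126 AAV subjects at
  diagnosis (52% with a matched remission sample, a few with relapse)
  plus 121 GCA, 63 PMR and 171 HC singletons × 118 antigens.

Background per-antigen prevalences follow a sharply skewed profile
(most antigens rare, a few up to ~50%) tuned so the expected
autoantibody load per sample is ≈ 5.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .containers import AntigenRecord, IntensityMatrix, SampleRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_cohort",
    "phase_config",
]


@dataclass(frozen=True, eq=False)
class SimulationConfig:
    """Full specification of a synthetic cohort (deterministic given seed).

    ``prevalence`` maps group name → per-antigen planted-positivity
    probability vector (length ``n_antigens``). All log-scale parameters
    are natural-log standard deviations / means of multiplicative
    lognormal factors.
    """

    n_samples_per_group: dict
    n_antigens: int
    prevalence: dict
    baseline_log_mean: float = 6.2  # exp ≈ 500 arbitrary MFI units
    baseline_log_sd: float = 0.5
    noise_log_sd: float = 0.35
    sample_scale_log_sd: float = 0.3
    site_effect_log_sd: float = 0.1
    positive_effect_log_mean: float = 4.4  # exp ≈ 80-fold boost
    positive_effect_log_sd: float = 0.4
    longitudinal_fraction: float = 0.0
    relapse_fraction: float = 0.0
    positive_persistence: float = 0.9
    antigen_family_tag: str = ""
    seed: int = 0

    def __post_init__(self):
        if self.n_antigens < 1:
            raise ValueError("n_antigens must be >= 1")
        for group, n in self.n_samples_per_group.items():
            if n < 1:
                raise ValueError(f"group {group!r} needs at least 1 sample")
        for group, prev in self.prevalence.items():
            if group not in self.n_samples_per_group:
                raise ValueError(f"prevalence for unknown group {group!r}")
            prev = np.asarray(prev, dtype=float)
            if prev.shape != (self.n_antigens,):
                raise ValueError(
                    f"prevalence vector for {group!r} must have length {self.n_antigens}"
                )
            if ((prev < 0) | (prev > 1)).any():
                raise ValueError("prevalence probabilities must lie in [0, 1]")
        missing = set(self.n_samples_per_group) - set(self.prevalence)
        if missing:
            raise ValueError(f"missing prevalence for group(s): {sorted(missing)}")
        for name in (
            "baseline_log_sd",
            "noise_log_sd",
            "sample_scale_log_sd",
            "site_effect_log_sd",
            "positive_effect_log_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("longitudinal_fraction", "relapse_fraction", "positive_persistence"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def __eq__(self, other):
        if not isinstance(other, SimulationConfig):
            return NotImplemented
        return self.to_json() == other.to_json()

    def __hash__(self):
        return hash(self.to_json())

    def to_json(self) -> str:
        payload = asdict(self)
        payload["prevalence"] = {
            g: list(np.asarray(v, dtype=float)) for g, v in self.prevalence.items()
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        payload = json.loads(text)
        payload["prevalence"] = {
            g: np.asarray(v, dtype=float) for g, v in payload["prevalence"].items()
        }
        return cls(**payload)


@dataclass
class SyntheticTruth:
    """Planted ground truth: binary positivity per sample × antigen."""

    positivity: pd.DataFrame
    prevalence_used: dict
    config: SimulationConfig


def _rng(seed: int, label: str) -> np.random.Generator:
    # stable per-stage substream: adding a group never perturbs another's draws
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    )


_SITE_WEIGHTS = {
    # loosely mirrors a three-site recruitment: vasculitis patients from
    # all sites, disease controls from one, healthy controls from two
    "AAV": (("MUW", 0.30), ("UCAM", 0.57), ("UMCG", 0.13)),
    "GCA": (("UMCG", 1.0),),
    "PMR": (("UMCG", 1.0),),
    "HC": (("UCAM", 0.55), ("UMCG", 0.45)),
}


def _sample_metadata(config: SimulationConfig, group: str, subject_ids):
    rng = _rng(config.seed, f"metadata:{group}")
    sites, weights = zip(*_SITE_WEIGHTS.get(group, (("SYNTH", 1.0),)))
    n = len(subject_ids)
    site = rng.choice(sites, size=n, p=np.asarray(weights) / sum(weights))
    sex = rng.choice(["M", "F"], size=n, p=[0.5, 0.5])
    age = np.clip(np.round(rng.normal(64, 12, size=n)), 19, 90).astype(int)
    meta = {"site": site, "sex": sex, "age": age}
    if group == "AAV":
        serotype = rng.choice(["MPO", "PR3", "negative"], size=n, p=[0.42, 0.52, 0.06])
        phenotype = np.where(
            serotype == "MPO",
            np.where(rng.random(n) < 0.72, "MPA", "GPA"),
            np.where(
                serotype == "PR3",
                np.where(rng.random(n) < 0.78, "GPA", "MPA"),
                np.where(rng.random(n) < 0.5, "MPA", "GPA"),
            ),
        )
        meta.update(
            serotype=serotype,
            phenotype=phenotype,
            on_treatment=rng.random(n) < 0.5,
            bvas=rng.poisson(15, size=n),
            organ_kidney=rng.random(n) < 0.55,
            organ_ENT=rng.random(n) < 0.40,
            organ_respiratory=rng.random(n) < 0.45,
        )
    return meta


def generate_cohort(config: SimulationConfig):
    """Generate (IntensityMatrix, sample records, antigen records, truth).

    Deterministic and bit-for-bit reproducible for a given config
    (including its seed).
    """
    m = config.n_antigens
    rng_antigen = _rng(config.seed, "antigens")
    baselines = np.exp(
        rng_antigen.normal(config.baseline_log_mean, config.baseline_log_sd, size=m)
    )
    antigen_ids = [f"AG{i:03d}" for i in range(m)]
    starts = rng_antigen.integers(1, 1500, size=m)
    lengths = rng_antigen.integers(40, 101, size=m)
    antigen_records = [
        AntigenRecord(
            antigen_id=antigen_ids[i],
            gene_symbol=f"GENE{i:03d}",
            uniprot_id=f"SYN{i:05d}",  # synthetic placeholder accession
            aa_start=int(starts[i]),
            aa_end=int(starts[i] + lengths[i] - 1),
            family_tag=config.antigen_family_tag,
        )
        for i in range(m)
    ]

    rng_site = _rng(config.seed, "sites")
    site_effects = {
        s: float(np.exp(rng_site.normal(0.0, config.site_effect_log_sd)))
        for s in ("MUW", "UCAM", "UMCG", "SYNTH")
    }

    sample_records: list[SampleRecord] = []
    truth_rows: list[np.ndarray] = []
    value_rows: list[np.ndarray] = []

    for group in sorted(config.n_samples_per_group):
        n_subjects = config.n_samples_per_group[group]
        prev = np.asarray(config.prevalence[group], dtype=float)
        rng_truth = _rng(config.seed, f"truth:{group}")
        rng_noise = _rng(config.seed, f"intensity:{group}")
        subject_ids = [f"{group}{i:03d}" for i in range(n_subjects)]
        meta = _sample_metadata(config, group, subject_ids)

        diag_truth = (rng_truth.random((n_subjects, m)) < prev).astype(np.int8)

        if group == "AAV":
            n_long = int(round(config.longitudinal_fraction * n_subjects))
            n_relapse = int(round(config.relapse_fraction * n_subjects))
            timepoints_by_subject = [
                ["diagnosis"]
                + (["remission"] if i < n_long else [])
                + (["relapse"] if i < n_relapse else [])
                for i in range(n_subjects)
            ]
        else:
            timepoints_by_subject = [["single"] for _ in range(n_subjects)]

        for i, subject in enumerate(subject_ids):
            for timepoint in timepoints_by_subject[i]:
                if timepoint == "remission":
                    keep = rng_truth.random(m) < config.positive_persistence
                    truth = diag_truth[i] * keep.astype(np.int8)
                else:  # diagnosis, relapse and single reuse the base truth
                    truth = diag_truth[i]
                scale = np.exp(rng_noise.normal(0.0, config.sample_scale_log_sd))
                boost = np.where(
                    truth == 1,
                    np.exp(
                        rng_noise.normal(
                            config.positive_effect_log_mean,
                            config.positive_effect_log_sd,
                            size=m,
                        )
                    ),
                    1.0,
                )
                noise = np.exp(rng_noise.normal(0.0, config.noise_log_sd, size=m))
                values = scale * site_effects[meta["site"][i]] * baselines * boost * noise
                suffix = {"single": "s", "diagnosis": "dx", "remission": "rem", "relapse": "rel"}[
                    timepoint
                ]
                record = SampleRecord(
                    sample_id=f"{subject}_{suffix}",
                    subject_id=subject,
                    group=group,
                    site=str(meta["site"][i]),
                    timepoint=timepoint,
                    anca_serotype=str(meta["serotype"][i]) if group == "AAV" else "unknown",
                    phenotype=str(meta["phenotype"][i])
                    if group == "AAV"
                    else "not_applicable",
                    sex=str(meta["sex"][i]),
                    age=float(meta["age"][i]),
                    on_treatment=bool(meta["on_treatment"][i]) if group == "AAV" else None,
                    bvas=(
                        int(meta["bvas"][i])
                        if group == "AAV" and timepoint in ("diagnosis", "relapse")
                        else (0 if group == "AAV" else None)
                    ),
                    organ_involvement=frozenset(
                        organ
                        for organ in ("kidney", "ENT", "respiratory")
                        if group == "AAV" and meta[f"organ_{organ}"][i]
                    ),
                )
                sample_records.append(record)
                truth_rows.append(truth)
                value_rows.append(values)

    sample_ids = [r.sample_id for r in sample_records]
    matrix = IntensityMatrix(
        pd.DataFrame(np.vstack(value_rows), index=sample_ids, columns=antigen_ids)
    )
    truth = SyntheticTruth(
        positivity=pd.DataFrame(
            np.vstack(truth_rows), index=sample_ids, columns=antigen_ids, dtype=np.int8
        ),
        prevalence_used={g: np.asarray(v, float) for g, v in config.prevalence.items()},
        config=config,
    )
    return matrix, sample_records, antigen_records, truth


def _background_profile(m: int, max_prevalence: float, exponent: float) -> np.ndarray:
    """Skewed per-antigen prevalence profile: most antigens rare, a few common.

    Interleaved so prevalence is not monotone in antigen index.
    """
    u = np.linspace(0.0, 1.0, m)
    profile = 0.001 + max_prevalence * u**exponent
    order = np.argsort((np.arange(m) * 47) % m)  # deterministic scramble
    return profile[order]


def phase_config(phase: str, seed: int = 0) -> SimulationConfig:
    """Ready-made study designs mirroring a broad (phase2) and a focused
    kinesin-family (phase3) bead-array screen.

    phase2: 126 AAV + 168 HC × 151 antigens. Antigen AG000 is planted as
    a rare AAV-enriched hit (≈5% vs ≈0.6%) and AG001 as a common weakly
    enriched one (≈16% vs ≈10%).
    phase3: 126 AAV (with matched remission samples for 52% of subjects
    and relapse for a few) + 121 GCA + 63 PMR + 171 HC × 118 antigens;
    AG000 is planted AAV-enriched (≈12% vs ≈3%).
    """
    if phase == "phase2":
        m = 151
        base = _background_profile(m, 0.35, 10)  # mean ≈ 0.033 → load ≈ 5
        prev = {g: base.copy() for g in ("AAV", "HC")}
        prev["AAV"][0], prev["HC"][0] = 0.048, 0.006
        prev["AAV"][1], prev["HC"][1] = 0.16, 0.10
        return SimulationConfig(
            n_samples_per_group={"AAV": 126, "HC": 168},
            n_antigens=m,
            prevalence=prev,
            seed=seed,
        )
    if phase == "phase3":
        m = 118
        base = _background_profile(m, 0.5, 12)  # mean ≈ 0.04 → load ≈ 4.7
        prev = {g: base.copy() for g in ("AAV", "GCA", "PMR", "HC")}
        prev["AAV"][0] = 0.12
        for g in ("GCA", "PMR", "HC"):
            prev[g][0] = 0.03
        return SimulationConfig(
            n_samples_per_group={"AAV": 126, "GCA": 121, "PMR": 63, "HC": 171},
            n_antigens=m,
            prevalence=prev,
            longitudinal_fraction=65 / 126,
            relapse_fraction=5 / 126,
            antigen_family_tag="kinesin",
            seed=seed,
        )
    raise ValueError("phase must be 'phase2' or 'phase3'")


def null_config(phase: str, seed: int = 0) -> SimulationConfig:
    """Phase-shaped config with identical prevalence in every group.

    Used for type-I calibration: any between-group difference found on
    such a cohort is a false positive.
    """
    config = phase_config(phase, seed=seed)
    groups = sorted(config.prevalence)
    base = _background_profile(config.n_antigens, 0.35 if phase == "phase2" else 0.5,
                               10 if phase == "phase2" else 12)
    return replace(config, prevalence={g: base.copy() for g in groups})
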