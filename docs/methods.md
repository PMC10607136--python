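# Methods

## Reactivity calling

Bead-array MFI values are positive, right-skewed and carry large
per-sample multiplicative scale differences (serum dilution, labeling,
instrument drift). Calling is therefore per sample, across all antigens
on the same array, using the median and the median absolute deviation
(raw MAD, no consistency constant):

- cutoff = `median(x) + n · MAD(x)`; a value is reactive when strictly
  greater than the cutoff. Ties with the cutoff are negative — "strictly
  greater" avoids over-calling on discretized intensities. A
  `greater_equal` mode and a 1.4826 consistency-constant switch exist but
  are off by default, matching the formula as conventionally written for
  this assay family.
- the continuous analogue is the nMAD score
  `(x_i − median(x)) / MAD(x)`; with the consistency constant off,
  strict-greater calling at multiplier `n` is identically `nMAD > n`.
  This identity is asserted in the test suite on random matrices.
- both statistics are invariant to rescaling a sample's vector by any
  positive constant, so arbitrary intensity units are harmless.

The multiplier `n` is assay-specific. The package ships the published
presets (planar 30, broad targeted bead array 50, focused kinesin bead
array 20) and, because the original per-assay derivation of `n` is not
reproducible from the available description, a deterministic surrogate:
scan a candidate grid ascending and pick the smallest `n` for which no
antigen's cohort-wide positivity exceeds a configurable cap (default
0.5). The chosen `n` is monotone in the cap, and the diagnostic table
reports per-candidate positivity distributions.

Degenerate samples (MAD = 0, e.g. a saturated or empty well) cannot be
calibrated: they are flagged, receive no calls and NaN nMAD scores by
default; a `min_mad` fallback substitutes the smallest nonzero MAD in
the cohort when retaining them is preferable. QC ahead of calling drops
samples whose fraction of valid (finite, positive) measurements falls
below a threshold (default 0.9) — a deterministic, auditable stand-in for
ad-hoc "technical exclusion" decisions — and logs every exclusion.

## Group statistics

Seroprevalence comparisons use the exact Fisher test with the two-sided
point-probability convention (sum of hypergeometric probabilities of all
tables with the observed margins whose probability is at most the
observed one, with 1e-7 relative slack for floating-point ties). The
implementation is cross-checked in the tests against exact-rational
fixed-margin enumeration on every 2×2 table with total ≤ 24, and against
an independent library implementation on random tables. Odds ratios are
unconditional; a 0.5 Haldane correction is applied (and flagged) only
when a cell is zero. Fisher is exact-conditional and therefore
conservative when expected counts are tiny: on cohorts where most
antigens have near-zero prevalence the realized false-positive fraction
at α = 0.05 is well below 0.05. The null-calibration check consequently
uses a flat moderate-prevalence (0.15) design, where the discreteness is
mild and the pooled rejection fraction is expected to sit inside the 99%
binomial interval of the nominal level.

Autoantibody-load comparisons use the Mann–Whitney–Wilcoxon test for two
groups — exact full permutation enumeration for combined n ≤ 20 (valid
in the presence of ties), otherwise the tie- and continuity-corrected
normal approximation — and Kruskal–Wallis for three or more.
Covariate correlations (age, disease-activity score) are Spearman with
listwise exclusion of missing pairs; missing clinical values are never
imputed for testing. Multiple-testing adjustment (Benjamini–Hochberg) is
available but off by default, since prevalence scans of this kind are
conventionally reported unadjusted and flagged as exploratory.

The PCA batch check mean-centers antigens, mean-imputes the (flagged)
NaN scores of degenerate samples, and reports per-sample component
scores plus explained-variance fractions for grouping by site and
diagnosis.

## Panels and ROC

A panel combines a few antibodies by a k-of-m rule on binary calls
(k = 1 is the elementwise OR, k = m the AND) or by a continuous score.
Because the original intensity-combination function for panels is not
stated anywhere reproducible, the default score is the sum of nMAD
scores over the panel (max and count-of-positives alternatives are
exposed); the count-of-positives score is the natural "binary data"
ROC input, giving the stepwise curve such data implies. This is an
explicit surrogate, not a reconstruction.

ROC curves sweep thresholds at midpoints between adjacent unique scores
with ±inf sentinels; classification is score > threshold. The
trapezoidal AUC equals the Mann–Whitney rank AUC with ties counted ½ —
both are computed and asserted equal in the tests. Operating points:
Youden's J with ties broken toward higher specificity, or best
sensitivity at a specificity floor. Curve comparison uses a paired
bootstrap (default B = 2000) resampling samples with replacement,
stratified by class so no resample is degenerate; the two-sided p-value
is the percentile position of zero in the AUC-difference distribution,
and the CI is the 2.5–97.5 percentile range. All resampling is
deterministic given the seed.

## ELISA verification

The ELISA cutoff is `mean + 3·SD` of the healthy-control OD450 readings,
with the sample (n−1) standard deviation — conventional for small
control panels; positivity is strict exceedance, and control wells are
never called. Under Gaussian null ODs this leaves ≈ 0.13% of null
samples above the cutoff, which the tests verify by simulation. ODs are
assumed blank-corrected upstream; no standard-curve fitting is modeled
because the verification assay is cutoff-based only. Cross-platform
concordance tabulates bead-array vs ELISA calls as a 2×2 table with an
exact Fisher p.

## Longitudinal comparisons

Matched series are built per subject (≥ 2 timepoints; singletons logged
and dropped). Load changes use the two-sided Wilcoxon signed-rank test
on within-subject differences with zeros dropped; an all-zero cohort is
reported as p = 1 with a degenerate flag rather than an error.
Per-antigen serostatus changes use the exact McNemar binomial test on
discordant pairs (p = 1 when none). The original analyses never name
their longitudinal tests; these two are declared surrogates consistent
with the nonparametric toolkit used everywhere else. Relapse samples are
few by design and treated descriptively.

## Synthetic cohorts

The generator emulates the data structure the pipeline targets, not any
particular instrument:

- intensity = sample scale × site effect × antigen baseline ×
  (positive boost, if planted) × noise, every factor lognormal. Defaults:
  baseline location log 500 (arbitrary units), baseline spread 0.5,
  measurement noise 0.35, sample scale spread 0.3, site effect spread
  0.1, positive boost location log 80 with spread 0.4 (all natural-log
  scale). Lognormal backgrounds with sparse strong positives are exactly
  the shape the median/MAD statistic presupposes; raw MFI scales are
  arbitrary because calling is scale-invariant.
- planted positivity per (group, antigen) follows a configured
  probability map. The ready-made designs use a sharply skewed
  background profile (most antigens near-zero, a few up to ~50%
  prevalence, deterministically interleaved) calibrated so the expected
  autoantibody load is ≈ 5 per sample with single-sample maxima in the
  low teens — the scale reported for real protein-fragment arrays. The
  `phase2` design (126 AAV + 168 HC × 151 antigens) additionally plants
  one rare strongly enriched antigen (≈5% vs ≈0.6%) and one common
  weakly enriched antigen (≈16% vs ≈10%) in the patient group; `phase3`
  (126 AAV with 52% matched remission and a few relapse samples, + 121
  GCA + 63 PMR + 171 HC × 118 antigens) plants one enriched antigen
  (≈12% vs ≈3%).
- longitudinal truth: a diagnosis-time positive persists at remission
  with probability 0.9 by default; relapse reuses the diagnosis truth.
  Clinical covariates (serotype, phenotype, sex, age, treatment,
  activity score, organ flags) are drawn with realistic frequencies and
  the usual serotype–phenotype association, but carry no planted
  antibody associations.
- randomness: one root seed; each stage and group draws from its own
  deterministically derived substream, so adding a group never perturbs
  another group's data, and identical (config, seed) reproduces output
  bit-for-bit.

What passing recovery tests show — and what they do not: with a strong
planted effect (boost ≈ 150×) the calling step recovers planted truth
with sensitivity ≥ 0.95 and specificity ≥ 0.99 on the phase3-shaped
design, and per-(group, antigen) called prevalence sits inside the 99%
binomial interval of the planted prevalence. With ~472 such cells at
nominal 99% coverage, ≈ 1% of cells are expected outside by chance, so
the recovery assertion requires ≥ 97% of cells inside rather than all —
an aggregation choice, not a widened per-cell band. None of this
demonstrates performance on real sera, where cross-reactivity,
antigen-specific backgrounds and plate effects are richer than the
lognormal model; the simulation validates the statistical machinery, not
the assay.

## Problem sizes and numerical choices

The simulation-based checks use the cohort sizes of the ready-made
designs (294 × 151 and 551 × 118 matrices; 8 replicate cohorts pooled
for the null-calibration scan), which keeps the full test suite and the
acceptance script in the tens-of-seconds range. Floating-point ties in
the Fisher tail sum use 1e-7 relative slack; ROC/rank AUC agreement is
asserted to 1e-10; exact-rational oracles (fractions arithmetic) back
the Fisher and McNemar tests. Degenerate inputs (constant samples, zero
discordant pairs, one-class ROC labels, unattainable specificity
targets) are either flagged results or informative errors, never silent.
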