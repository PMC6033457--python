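# Methods

This note documents the models, conventions and design choices behind
`adchist`, and what the synthetic-data tests do and do not establish
about real data.

## ADC estimation

ADC maps use the two-point log-ratio solution of the mono-exponential
decay model, by default from b = 500 and 1000 s/mm² (the b = 0 volume,
when present, is not used for ADC: perfusion contaminates the low-b
signal, and the two higher b-values isolate diffusion). No multi-point
least-squares fit is offered; with two points the log-ratio *is* the
maximum-likelihood solution under log-normal noise.

Unit convention: mm²/s internally everywhere; serialization and reports
rescale to ×10⁻³ mm²/s (columns suffixed `_e3`).

Degenerate signals: a voxel with a nonpositive signal at either b-value
is flagged invalid and excluded, never clamped — clamping would
fabricate extreme ADC values that land in the outer pADC bins and
distort exactly the quantity the analysis rides on. Negative ADC
estimates (noise inverting the ratio) are retained, because the lowest
histogram bin is unbounded below; their count is reported.

Multi-slice ROIs are pooled into a single voxel population (no per-slice
weighting). The optional extreme-slice exclusion drops the first and
last ROI-bearing slices — a partial-volume guard at the tumor poles —
and is ignored with a warning when the ROI spans fewer than three
slices. It defaults to off for synthetic phantoms, which have no
partial-volume contamination to guard against.

## Histogram features

Skewness and excess kurtosis use population moments (denominator N, no
Fisher small-sample correction), so a normal population tends to
(0, 0). This matters for cross-language reproduction: R's `e1071`
types 1–3 and SciPy's `bias=False` variants differ at n ≤ 30 by more
than the group differences studied here.

pADC bins are closed on the left — a voxel exactly at 0.6 ×10⁻³ mm²/s
belongs to the *low* bin, not the *extremely low* bin. The median of an
even-length vector is the mean of the two central order statistics.
Group summaries print sample (N−1) standard deviations; single-case
groups print no sd.

## Group statistics

Cohen's d is stored signed (first group minus second, with the deceased
group conventionally first) and additionally exposed as a magnitude,
which is how such tables are usually printed. Welch's test keeps the
fractional Welch–Satterthwaite degrees of freedom.

The Freeman–Halton test enumerates all 2×k tables with the observed
margins (budget `prod(col_j + 1) ≤ 10⁶`, else a capacity error advises
Monte-Carlo). The two-sided p-value follows the probability-mass rule —
total probability of tables no more probable than the observed one,
with 10⁻¹² absolute slack — which reduces to the classical two-sided
Fisher test at k = 2. Other orderings (Pearson chi-square,
likelihood-ratio) exist in the literature; the probability rule is the
one implemented by R's `fisher.test` and was validated against it and
against a brute-force enumeration oracle.

## Prognostic models

The univariate Cox partial likelihood is maximised by Newton iteration
with step halving on a standardized covariate, to gradient norm
< 10⁻⁸. Efron tie handling is the default (the cohort design has tied
event months); Breslow is a config option. Monotone likelihood
(a covariate that perfectly orders the event times) has no finite
maximiser; it is detected (|β| > 15 per covariate sd) and reported as
`converged = False` rather than returned silently. Hazard/odds ratios
are `exp(β · unit_scale)` with Wald 95% intervals; unit scales follow
the conventional reporting of this analysis (ADC mean/median per
1×10⁻⁴ mm²/s, pADC per 1%, moments per 1 unit, TNM per grade, binary
contrasts for age ≥ 60, margins, and adjuvant treatment).

The proportional-hazards diagnostic is the scaled-Schoenfeld-residual
slope test with Kaplan–Meier time transform (lifelines), α = 0.05;
predictors that fail are excluded from the Cox table with an explicit
marker (age is the canonical example in this cohort design). Cohorts
with fewer than three events return an explicitly undefined result.

ROC analysis: AUC is the Mann–Whitney concordance with ties counted
one half. Cutoffs maximise Youden's J; ties resolve toward higher
specificity, then toward the more conservative threshold. Candidate
thresholds sit midway between adjacent distinct scores (plus the
all-positive extreme) rather than on the observed values: a midpoint
separates a separable boundary case correctly on both sides of the gap,
which also makes leave-one-out classification of a held-out boundary
patient exact in the separable case. LOOCV refits only the cutoff per
fold (threshold-based prediction, not a per-fold logistic model); a
config flag reuses one fixed cutoff in every fold instead. Training
folds that lose an outcome class fall back to the majority class and
are flagged.

## Synthetic data generator

**Image level.** Tumors are ellipsoids on a coarse head-and-neck-like
grid (default 1.8×1.8×4 mm voxels) partitioned into spatially
contiguous compartments; each compartment draws voxel ADC from a normal
truncated at zero. DWI signals follow `S0 exp(-b ADC)` with Rician
noise (magnitude of a two-channel complex Gaussian perturbation), the
physical model for magnitude MR images; a zero-noise mode supports
exactness tests. At low SNR the Rician floor inflates the high-b signal
relatively more and biases extracted ADC low — a documented property
asserted by a seeded sign test, not corrected for.

**Cohort level.** Feature distributions are truncated normals
parameterised by their *post-truncation* mean and sd; the parent
(μ, σ) are solved numerically so the truncated distribution reproduces
the configured group summaries. This matters: naively truncating
N(34.3, 24.8²) at zero would shift the realized mean to ≈ 38, so the
generated cohorts would not emulate the summaries they are configured
with. The truncated-normal family bounds the attainable coefficient of
variation (cv → 1 in the exponential-like limit for support far from
the upper bound); configured targets exceeding it (e.g. survivors'
pADC < 0.6 at 5.1 ± 5.2) match the mean exactly while the sd saturates
at its feasible maximum. Sampling is inverse-CDF, so draws are a pure
function of their substream: patient *i* of a group derives from
`default_rng([seed, group_code, i])` and is reproducible independent of
cohort size.

The four pADC bins cannot be independent (they sum to 100): the
prognostically central bin (< 0.6) keeps its exact marginal and the
other three are rescaled to close the composition. Continuous features
are otherwise drawn independently within a group — the real correlation
structure (mean vs median, mean vs pADC) is *not* emulated, so passing
tests say nothing about multivariable behaviour on real data; this is
one reason the analysis stays univariate.

Outcomes: in the default mode the deceased group receives uniform event
times in 5–18 months and survivors uniform censoring in 42–136 months,
mirroring the reference cohort's follow-up structure; the binary 3-year
outcome coincides with the event flag. The hazard-model mode instead
draws exponential event times log-linear in one predictor with
administrative censoring at 136 months, for parameter-recovery studies.
TNM grades and binary clinical covariates draw from per-group frequency
tables consistent with the reference cohort's stated group sizes.

## Problem sizes used by the suite

Simulation-backed tests use sizes chosen to make the asserted bands
stable at fixed seeds: moment convergence at 10⁶ draws; phantom
fraction recovery at ≥ 10⁴ voxels (2-point tolerance); Cox/logistic
parameter recovery at n = 500 (3 SE); PH-diagnostic type-I error over
200 replicates of n = 100 and power over 40 replicates of n = 300 with
a sign-flip at 20 months; generator mean calibration over 300 cohorts;
and the LOOCV accuracy band over 500 seeded default cohorts (mean in
[0.75, 0.95], measured ≈ 0.83). Per-patient quantities of the original
study (AUC 0.929, cutoff 8.3%, LOOCV 90%) depend on unpublished
per-patient data and are reproduced only as such distributional bands.

## Known limitations

- No DICOM ingestion, registration, eddy-current or susceptibility
  correction; NIfTI volumes are assumed co-registered.
- No IVIM bi-exponential separation of perfusion from diffusion.
- Multivariable Cox/logistic models are out of scope (unidentifiable at
  n = 20 and not emulated by the generator's independence structure).
- ADC values are scanner- and sequence-dependent; nothing here
  harmonizes ADC across acquisition protocols.
- The Freeman–Halton implementation is exact-enumeration only; very
  large tables need an external Monte-Carlo approach.
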