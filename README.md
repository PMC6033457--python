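# adchist

ADC histogram profiling and univariate prognostic modelling for
diffusion-weighted MRI (DWI) tumor cohorts, built for the setting of
salivary gland carcinoma, where heterogeneous cancer nests with dense
cellularity restrict water diffusion and depress the apparent diffusion
coefficient (ADC) in part of the tumor.

The package is aimed at imaging researchers who want a tested, scriptable
reimplementation of the ADC-histogram prognostic workflow — from raw DWI
signal volumes to effect sizes, regression tables and cross-validated
threshold classifiers — together with a seeded synthetic phantom/cohort
generator so that every stage can be exercised and validated without
patient data.

## What it computes

**ADC mapping.** Under mono-exponential decay `S(b) = S0 exp(-b ADC)`,
two acquisitions at b-values `b_low < b_high` (default 500 and
1000 s/mm²) give, voxel-wise,

    ADC = ln(S_low / S_high) / (b_high - b_low)   [mm²/s]

Voxels with nonpositive signal are flagged invalid (never clamped);
negative estimates from noise are kept but counted.

**Histogram profile.** Pooled over the tumor ROI (optionally dropping
the first and last ROI-bearing slices): mean, median, population-moment
skewness `E(x-μ)³/σ³` and excess kurtosis `E(x-μ)⁴/σ⁴ − 3`, and the
four-bin pADC percentages with closed-left bins
`<0.6`, `[0.6, 1.2)`, `[1.2, 1.8)`, `≥1.8` (×10⁻³ mm²/s).

**Group statistics.** Welch's unequal-variance t test, the
Freeman–Halton exact test for 2×k contingency tables (probability-mass
two-sided rule), and Cohen's d with the pooled SD

    d = (M₁ − M₂) / SD_pooled,
    SD_pooled = sqrt([SD₁²(N₁−1) + SD₂²(N₂−1)] / (N₁+N₂−2))

**Prognostic models.** Per predictor: univariate Cox proportional
hazards (Newton on the Efron — optionally Breslow — partial likelihood,
Wald CIs, hazard ratios per stated covariate unit), a
scaled-Schoenfeld-residual proportional-hazards diagnostic, univariate
logistic regression with separation detection, ROC analysis (AUC as the
tie-corrected Mann–Whitney statistic, Youden-J cutoff), and
leave-one-out cross-validation of the single-threshold classifier.

**Synthetic data.** Ellipsoidal multi-compartment DWI phantoms with
Rician noise, and cohort tables whose group-conditional feature
distributions default to the reference study's summaries (6 deceased vs
14 survivors; events at 5–18 months, survivors censored at 42–136
months), with an optional exponential-hazard generating mode.

## Worked example

Effect size and Welch test for the percentage tumor area with extremely
low ADC (< 0.6 ×10⁻³ mm²/s) between outcome groups, straight from group
summaries:

```python
from adchist import GroupSummary, cohens_d, welch_test

doc  = GroupSummary(mean=34.3, sd=24.8, n=6)   # died of cancer < 3 y
surv = GroupSummary(mean=5.1,  sd=5.2,  n=14)  # survived > 3 y
es = cohens_d(doc, surv)
w  = welch_test(doc, surv)
print(f"|d| = {es.magnitude:.2f} (pooled SD {es.sd_pooled:.1f}), Welch p = {w.p:.3f}")
```

prints

```
|d| = 2.12 (pooled SD 13.8), Welch p = 0.034
```

i.e. a very large standardized separation between deceased and surviving
patients on this parameter, significant at the 5% level despite n = 20.

The full synthetic pipeline runs from the shell:

```
adchist run --seed 1 --out-dir out/
```

which simulates a 6 + 14 cohort, writes `out/cohort.csv`, the group
comparison, Cox and logistic/ROC tables, a LOOCV accuracy, and a
human-readable `out/report.txt`. Individual verbs (`simulate`,
`adcmap`, `roivals`, `extract`, `groupstats`, `analyze`, `crossval`)
expose each stage separately.

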