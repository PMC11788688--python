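# Methods

## Dose metrics

All dose-response inputs are biologically effective doses under the
linear-quadratic model, `BED = n·d·(1 + d/(α/β))` with α/β = 10 Gy unless a
model specifies otherwise.  Two BEDs are carried per patient: the
prescription-dose BED (`bed_pd_gy`) and the maximum/isocenter BED in the
target (`bed_dmax_gy`, always ≥ the prescription value).  Which column
feeds which model is a per-model config key; the shipped default maps every
model to `bed_dmax_gy`, because with the median cohort covariates the
isocenter dose reproduces the characteristic median predictions of all
three logistic models simultaneously, whereas the prescription dose does
not.  The regrowth-corrected BED subtracts `(ln2/(α·T_p))·Γ` for elapsed
treatment time Γ (days); it equals the plain BED at Γ = 0 and never exceeds
it.

The probit (Liu-type) model re-expresses each schedule at its own α/β
(default 20 Gy, consistent with the steep low-dose behaviour that model is
known for).  Because the cohort schema stores BED₁₀ rather than the raw
fraction dose at the isocenter, the per-fraction dose is recovered by
inverting the LQ relation (positive quadratic root) before re-expressing.

### Time units and the two doubling times

Treatment-time quantities (Γ, T_p) are in days; follow-up horizons are in
years and converted by `tau_unit_days` (365.25).  The model glossary this
package follows defines a doubling time both for intra-treatment regrowth
(in the corrected BED) and for post-treatment regrowth (in the probit
argument); whether these are the same quantity is ambiguous in the source
material, so they are exposed as two config keys (`t_p_regrowth_days`,
`t_p_postrx_days`) with equal defaults.  Likewise the grouping of the
regrowth exponent `α·BED − (ln2/T_p)·τ·δ` (δ multiplying the whole regrowth
term) is isolated in a single function, `liu_t_statistic`, so an alternative
reading needs a one-line change.

## Model parameters

Published values are shipped for the three logistic models (Ohri:
c = 10 Gy/cm, TCD₅₀ = 0 Gy, k = 31 Gy; gucken: TCD₅₀ = −1 Gy, k = 80 Gy;
santiago: TCD₅₀ = −60.2 Gy, k = 113.3 Gy).  The Liu and Klement
coefficients are **synthetic placeholders**, chosen once for clinical
plausibility and flagged as such in the default config: the Liu defaults
(α = 0.3 /Gy, T_p = 3 d, δ = 0.01, K_cr = 1, σ_k = 0.6, clonogen density
10⁷ /cm³ with K₀ = ρ·(π/6)·L³) give a steep probit transition near
BED₂₀ ≈ 60 Gy, a high-dose plateau near 0.95 and only a minor 2→3-year
decline; the Klement defaults (θ = 0.4, ρ = 1.5, η intercept −1.5 with a
dominant negative dose coefficient) give a cure plateau of e^(−0.4) ≈ 0.67
and an ~7-point decline from 2 to 3 years.  θ may alternatively be
covariate-dependent through a log-linear link; the scalar form is the
default.  Covariate standardisation references default to the scored
cohort's own moments and can be overridden with the training-population
moments, which a faithful external validation requires.

Numerical guard: the probit survival function underflows for the Liu
model's low-dose tail, so its output is clipped to [1e−300, 1 − 1e−16] to
keep predictions inside the open unit interval.

## Synthetic cohort generator

The generator emulates a lung-SBRT population of 153 patients: 75.2% male;
age log-normal matched to median 65/IQR 16; stage I/II/III/IV at
31.4/9.2/6.5/52.9%; 60.8% primary; 86.9% peripheral; diameter log-normal
matched to median 3.2 cm/IQR 2.6; a dose-schedule frequency table headed by
12.5 Gy×4 (17.6%), 10 Gy×5, 25 Gy×1, 10 Gy×4, 12 Gy×4 and 24 Gy×1, with the
remaining 42.6% split across six additional invented-but-standard regimens;
treatment duration built from a log-normal inter-fraction spacing (median
2 d) so 4 fractions take ~7 days.  Log-normals are used because the
emulation targets are positive, right-skewed and only summarised by median
and IQR (σ = asinh(IQR/2m)/z₀.₇₅).  Diameter and schedule are linked by a
Gaussian copula (ρ = 0.4, schedules ordered by fraction count) to mimic
risk-adapted prescribing — the dependence is invented, not estimated.  The
isocenter dose exceeds the prescription dose by a per-patient log-normal
factor (median ~11% per fraction), chosen so the BED_Dmax/BED_PD ratio is
near the ~1.2 observed in practice.  Prior-chemotherapy prevalence (0.3) is
not part of the emulation target and is invented.

Outcomes are Bernoulli draws from a chosen generating TCP model (default:
the Klement cure-rate model, the simplest generator valid at both
horizons).  The two horizons are coupled sequentially —
`lc₂ ~ Bern(TCP₂)`, then `lc₃ | lc₂=1 ~ Bern(TCP₃/TCP₂)` (clipped) — so
`lc₃ = 1 ⇒ lc₂ = 1` holds by construction.  A time-dependent generator
with TCP₃ > TCP₂ for any patient is rejected.  All draws flow from a
single spec-level seed via spawned `SeedSequence`s; identical specs give
byte-identical CSVs.

What the generator does **not** emulate: censoring and loss to follow-up,
overall survival and competing risks, correlated real-world miscalibration
(outcomes are calibrated to the generating model by construction), dose
heterogeneity beyond the single Dmax factor, and any covariate joint
structure beyond the diameter-schedule copula.  Passing tests therefore
demonstrate internal statistical correctness of the pipeline, not clinical
performance of the models on real data.

## Validation statistics

AUC is the Mann-Whitney concordance with ties counted ½; its variance, CIs
(normal approximation), the test against 0.5, and the paired test for two
correlated AUCs use DeLong structural components (implemented here; an
independent from-definitions re-implementation serves as the test oracle).
The Hosmer-Lemeshow statistic sums `(O−E)²/E` over the event and non-event
cells of quantile bins of predicted risk (ties kept together; bins with
zero expected events or non-events are merged into a neighbour and
logged).  Degrees of freedom: for *pre-specified* models — the external
validation setting, where no parameter was fitted to the scored data — the
appropriate reference is χ² with as many degrees of freedom as bins, and
that is the default (`df_policy="external"`); simulation at n = 153 with
the generating model scored on its own cohorts gives a ~6% type-I rate
under this policy versus ~14% under the classical `bins − 2` convention,
which remains available as `df_policy="fitted"`.  The chosen policy is
recorded in every report manifest.

Operating points use the Youden index (sensitivity + specificity − 1) over
the distinct observed scores, ties broken toward the higher threshold, and
the half-open convention score ≥ threshold ⇒ predicted positive.  The
positive class defaults to *local control* (so sensitivity is the
controlled-detection rate); a flag flips it to recurrence, complementing
both labels and scores.  Calibration-plot bins are flagged "over" when the
model predicts a higher probability than observed (over-confident) and
"under" in the opposite case.

Reporting conventions: medians and IQRs of predictions use linear
interpolation (type-7) quantiles; table percentages are printed to one
decimal; figures are SVG with a fixed hash salt so re-renders are
byte-stable; every bundle writes a manifest with the config SHA-256, seed,
library versions and the conventions above.

## Problem sizes

The shipped test and acceptance workloads use cohorts of 120-153 patients
(matching the emulated study size) for end-to-end checks, 10,000-100,000
synthetic patients for law-of-large-numbers and monotonicity properties,
and 200 replicate cohorts for the generating-model recovery and HL type-I
experiments — sizes at which the binomial tolerances quoted in the tests
(3 standard errors) are meaningful while the whole suite runs in seconds.

## Known limitations

* The shipped Liu/Klement coefficients are placeholders; conclusions about
  those models' real-world accuracy require the original fitted values.
* The HL statistic's χ² reference is asymptotic; with 153 patients and 10
  bins the simulated type-I rate (~6%) is close to but not exactly nominal.
* DeLong machinery materialises the m×n pairwise comparison matrix, which
  is fine for clinical cohort sizes but quadratic in memory.
* The generator's marginals are matched, not its joint distribution;
  covariate interactions in real cohorts may differ materially.
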