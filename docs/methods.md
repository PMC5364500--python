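# Methods

This note documents the models, estimators, numerical choices and
limitations behind `cvdrisk`, in the spirit of a statistical appendix.

## Risk equations

**Cox-form family.** An equation is a list of terms, each mapping one
covariate (or a product of two transformed covariates) to a coefficient.
Transforms: identity, natural log, half-open category bands `[lo, hi)`
partitioning the real line (referent bands carry coefficient 0), and
two-factor products (used for the PCE age interactions). A term may carry a
condition (e.g. the treated vs untreated systolic-pressure split); exactly
one coefficient then applies to any input. Absolute risk over horizon *h*:

    risk = 1 − S0(h) ^ exp(L − L̄),   L = Σ_j β_j f_j(x_j)

clipped to [0, 1]. `L̄` ("mean coefficient × value") is the population mean
of `L`; it is treated as an opaque scalar of the spec — for models without
interactions it coincides with `Σ β_j mean(f_j(x_j))`, with interactions it
is the mean over subjects of the full term, which is how the recalibrator
computes it.

**Weibull two-cause family (SCORE-style).** Per cause (coronary and
non-coronary CVD): baseline survival `S0(a) = exp(−exp(α)(a−20)^p)`,
proportional hazards on `w = β_chol(TC−6 mmol/L) + β_sbp(SBP−120 mmHg) +
β_smoke·smoker`, and the risk over *h* from age *a* is
`1 − [S0(a+h)/S0(a)]^exp(w)`; the two cause risks are summed and clipped.
The family is undefined at age ≤ 20 and the engine rejects such input.
These equations carry no per-covariate means, so recalibration for them is
limited to horizon evaluation and attachment of the diabetes multiplier
(×3 men, ×5 women, capped at 1 — applied after any clipping, because ×5
can exceed certainty). The shipped SCORE parameter files are *synthetic
placeholders* of plausible magnitude (flagged `synthetic: true`): the
original coefficients are licensed elsewhere and are deliberately not
transcribed; users supply their own spec files for real use.

**Units.** Canonical cohort units are SI (mmol/L, mmHg, kg/m², years).
Each spec declares the units its terms expect; conversion (38.67 mg/dL per
mmol/L for cholesterol, 18.02 for glucose) happens inside the engine at the
term boundary, so cohort files always stay in measured units.

**Horizon handling.** If a spec lacks `S0` at a requested horizon, the
engine can rescale under a constant-hazard-fraction assumption,
`S0(h) = exp(ln S0(H) · h/H)`. This is an explicit, overridable default;
when a target cohort is available the Breslow estimate from the
recalibration module is preferred.

## Validation statistics

**Discrimination.** AUC is Mann–Whitney concordance with half credit for
ties (computed via the grouped ROC); its confidence interval and the paired
two-model comparison use the DeLong structural-components estimator
(midrank algorithm). Sensitivity/specificity use the inclusive rule
(positive iff score ≥ cutoff) with exact Clopper–Pearson intervals;
likelihood ratios report `inf` on zero denominators. The "population"
operating point maximises Youden's J over observed score values (smallest
cutoff on ties) — the selection rule is recorded in output metadata since
several conventions exist.

**Calibration (Greenwood–Nam–D'Agostino).** Subjects are ranked into 10
quantile groups of predicted risk (ties kept together); any group with
fewer than 2 observed events is merged into the adjacent neighbour with the
closer mean predicted risk (edge groups merge inward; lowest-risk violator
first) until all groups comply. Per group the observed risk is
`1 − KM(h)` with the Greenwood variance of the Kaplan–Meier estimate, and

    χ² = Σ_g (KM_obs_g − p̄_g)² / Var_g,   df = G − 1.

The df = G − 1 convention is pinned by two published worked examples
(χ² = 5.109, G = 5 → P = 0.276; χ² = 2.917, G = 4 → P = 0.405). A binomial
variance `p̄(1−p̄)/n` is available as a switch; Greenwood is the default and
the choice is recorded in report metadata. Groups with zero variance are
excluded with a warning.

Two properties of this test matter for interpretation and shaped the
operating-characteristic suite:

1. *df convention vs the validated model.* When the model being tested is
   anchored to the validation population — its baseline survival and mean
   linear predictor estimated from the same cohort, which is exactly what
   every recalibrated model in this toolkit is — the overall
   observed-minus-expected difference is constrained near zero and the
   statistic loses about one degree of freedom, making df = G − 1 the
   right reference. For a fully external model the statistic behaves as
   χ²_G and the df = G − 1 test is mildly anti-conservative
   (≈ 7.6% at G = 10).
2. *Events per group.* The denominator is an estimated (Wald-type)
   variance; with fewer than ~25 events per group the statistic's tail is
   heavier than χ² and rejection rates inflate well above nominal
   (pilot simulations: 10–20% at 1.5–6% event rates).

The type-I-error suite therefore simulates the workflow the toolkit
actually applies — a correctly specified model, anchored to each simulated
cohort by the Breslow baseline + mean-LP replacement, with a 30% baseline
6-year risk so every decile holds ≥ 100 events (n = 5000, β = 0.5 on a
standard-normal covariate, exponential event times, administrative
censoring at the horizon). Under those conditions the measured rejection
rate at α = 0.05 is 0.050 (1000 replicates). Passing this suite says the
test holds its level *within the recalibrated workflow at adequate event
counts*; it does not certify behaviour for external models or sparse-event
groupings.

## Recalibration

* *mean-only*: keep coefficients, replace `L̄` by the cohort mean linear
  predictor and `S0(h)` by the cohort Breslow estimate.
* *full*: first refit all coefficients by Cox partial likelihood
  (lifelines) on a design matrix that reproduces the spec's structure
  exactly — one column per simple/product term (condition-masked), one
  indicator column per non-referent band. Band refits treat the
  coefficient-0 band as referent by construction.

The Breslow baseline is centered at the mean linear predictor:
`H0(h) = Σ_{event times t ≤ h} d_t / Σ_{j ∈ risk set} exp(L_j − L̄)` and
`S0(h) = exp(−H0(h))`, so a subject at `L = L̄` has survival `S0(h)` —
matching the risk formula. Refits require ≥ 30 events (configurable);
non-convergence, non-finite or wildly large coefficients (|β| > 1000,
a separation guard) raise a recalibration error. Recovery is verified by
simulation: on 20 000 subjects drawn from a known two-term model the
refit lands within 3 SE of truth and per-subject risks agree with the
generator to median |Δ| < 0.002.

Recalibrated specs carry provenance metadata (mode, 16-hex cohort hash,
horizon; an explicit date only if the caller passes one — the pipeline
omits it so identical config + seed reproduce byte-identical reports).

## Synthetic cohort generator

The generator emulates the *published marginal structure* of a middle-aged
rural Chinese cohort (sex-stratified means/SDs of age, total and HDL
cholesterol, fasting glucose, SBP, BMI; prevalences of smoking, diabetes,
hypertension and treatment; 38.16% male) and its outcome rates (1.6%
6-year CVD mortality, ~4.0% all-cause). Construction:

* Continuous block per sex through a Gaussian copula. Correlations are
  **not** published; an exchangeable 0.2 is a declared assumption
  (configurable matrix). Marginals are normal with a small positive floor,
  except age: a truncated normal on the [40, 65] eligibility window whose
  underlying parameters are solved so the *truncated* mean matches the
  published value exactly and the SD as closely as the family allows — the
  published age SDs (7.23/7.15) sit essentially at the truncation-width
  bound (25/√12 ≈ 7.22), so the realized SD is marginally smaller. Only
  means are asserted in the fidelity suite.
* Smoking and diabetes are independent per-sex Bernoulli draws at the
  published prevalences. Diabetes is deliberately *not* derived from the
  glucose marginal: a normal glucose distribution would put ~24% of women
  above the 7 mmol/L diagnostic threshold, contradicting the published
  10.1% prevalence; glucose is kept as a descriptive marginal only (the
  risk equations use the flag). Hypertension is `SBP ≥ 140` topped up by an
  independent Bernoulli to the published prevalence, and treatment is
  Bernoulli among the hypertensive — this preserves both the SBP marginal
  and the prevalence while keeping treated subjects mostly hypertensive.
* CVD death times are Weibull proportional hazards,
  `T = (−ln U / (λ e^{β'x}))^{1/k}`, with default shape k = 1.1 and
  log-hazard-ratio coefficients chosen once as epidemiologically plausible
  for CVD mortality at these ages (age 0.09/y, male 0.4, SBP 0.015/mmHg,
  TC 0.15, HDL −0.5 per mmol/L, smoking 0.5, diabetes 0.7; covariates
  centered at cohort-typical values). An independent second Weibull cause
  generates non-CVD deaths (censoring the CVD analysis); loss to follow-up
  defaults to zero, matching a cohort from which lost subjects were already
  excluded (person-years ≈ N × 6 minus death truncation). The two baseline
  scales were calibrated once by bisection with common random numbers
  (500 000 simulated subjects) to the 1.6% / 4.0% targets and frozen in the
  default config (λ_CVD = 1.054×10⁻³, λ_other = 2.347×10⁻³).
* A single master seed spawns per-stage substreams (continuous, binary,
  outcome, loss) via `numpy.random.SeedSequence`, so runs are exactly
  reproducible and stage-level edits do not perturb other stages.

What passing tests on this cohort do *not* show: fidelity of the joint
covariate distribution beyond the declared marginals + exchangeable
correlation, skewness of real glucose/lipid distributions, age–risk-factor
cohort effects, or real cause-of-death adjudication. Conclusions about the
*published* models' performance on the real cohort cannot be reproduced
here because the underlying data are not deposited; the synthetic cohort
validates the machinery, not the epidemiology.

## Problem sizes and tolerances

The default test suite uses: 1000 replicates × n = 5000 for the
calibration-test level; n = 20 000 for recalibration recovery (3 SE /
median |Δ| < 0.002); n = 50 000 for generator fidelity (3 SE on means, 99%
binomial interval on the event fraction); 1000 replicates × n = 500 for
the paired DeLong test's level. These sizes make the Monte-Carlo error
small relative to each tolerance while keeping the full suite under a
minute of compute. Bisection calibration of the baseline scale stops at
|rate − target| ≤ 0.001 on ≥ 200 000 simulated subjects.

## Known limitations

* Non-CVD deaths censor the CVD Kaplan–Meier (no competing-risks
  estimator); with ~2.4% competing mortality over 6 years the bias is
  negligible, but the choice matters at higher competing rates.
* The GND test is anti-conservative for sparse events (see above); the
  group-formation minimum of 2 events is the published convention, not a
  sufficiency guarantee.
* Constant-hazard-fraction horizon rescaling is an assumption; prefer
  cohort-estimated baselines.
* The published PCE-AA male column coincides numerically with the
  general-FRS male column; the fixture transcribes it as printed and flags
  the anomaly in its metadata.
* Risk-category thresholds are model-family conventions on 10-year risk;
  they are applied to whatever horizon is scored, as in the source
  validation design.
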