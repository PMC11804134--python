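# Methods

This note documents the statistical procedures `metsrisk` implements, the
assumptions of its synthetic cohort generator, and the numerical and design
choices made where conventions differ between software packages.

## Risk equations

A risk model is a fixed logistic equation: intercept plus per-predictor
log-odds coefficients with explicit encodings (reference levels: female,
white ethnicity, lower-metabolic-activity antipsychotic, non-smoker).
Continuous predictors (age in years, BMI in kg/m², HDL and triglycerides in
mmol/L) enter untransformed unless the config declares a transform. Any
development-time shrinkage is assumed folded into the published
coefficients; the package never re-derives them. Prediction is
deterministic; a record lacking a declared predictor raises a missing-data
signal rather than being silently imputed, and antipsychotics absent from
the metabolic-activity lookup raise an unknown-drug signal rather than
defaulting to a class, because silent exposure misclassification would
corrupt every downstream estimate.

## Outcome rule

Incident metabolic syndrome follows the IDF consensus: central obesity
(waist ≥ 94 cm male / 80 cm female; BMI > 30 substitutes only when waist is
unmeasured — when both are present waist governs) plus at least two of
triglycerides ≥ 1.7 mmol/L, HDL < 1.03 (male) / 1.29 (female) mmol/L,
SBP ≥ 130 or DBP ≥ 85 mmHg, fasting glucose ≥ 5.6 mmol/L. Cut-offs live in
a config object so ethnicity-specific waist thresholds can be supplied.
Treatment flags (lipid-lowering, antihypertensive or glucose-lowering
therapy) count the corresponding component as present; they default to
absent. The classifier is three-valued: it returns *indeterminate* exactly
when the missing components leave both verdicts reachable under some
completion of the data, which is decided by interval arithmetic on the
component count (minimum = components known satisfied, maximum = minimum +
unknown components).

## Eligibility

Six criteria in fixed order for first-failure reporting: age 16–35 at
diagnosis, treated by the service, baseline measures within ±100 days of
diagnosis (inclusive), no baseline metabolic syndrome, follow-up measures
1–6 years after baseline (inclusive), and data complete enough to classify
the outcome. Indeterminate baseline classifications are excluded
conservatively: a possibly-prevalent case must not enter an incidence
cohort.

## Validation metrics

* **C-statistic**: (concordant + ½·tied) / all case–non-case pairs,
  computed in O(n log n) from midranks; the test-suite verifies exact
  equality with the O(n²) pair count on random tied instances.
* **Calibration**: the reported *intercept* comes from the slope-fixed
  offset fit (GLM with the linear predictor as offset), the reported
  *slope* from the two-parameter logistic refit — the standard convention,
  under which the two numbers answer separate questions (overall
  under/over-prediction vs over/under-fitting).
* **Grouped calibration**: stable sort by predicted risk, ten near-equal
  bins with earlier bins absorbing remainders (deterministic under ties),
  Wilson 95% intervals for bin proportions — chosen because per-bin n ≈ 12
  in a 116-person cohort, where Wald intervals misbehave.
* **Nagelkerke R²**: Cox–Snell likelihood-ratio R² against the
  prevalence-only model, rescaled by its maximum and clipped to [0, 1].
* **Bootstrap CIs**: percentile intervals over outcome-stratified case
  resampling (2000 replicates by default). Stratification preserves the
  event count: at 13% prevalence and n = 116, unstratified replicates are
  occasionally event-free and the statistic undefined. If more than 10% of
  replicates fail the interval is refused rather than silently narrowed.
* **VIF**: 1/(1−R²) per design column, OLS with constant; exact
  collinearity reports infinity.

## Updating hierarchy

Transported models are updated at three levels, each reported separately:

1. *Intercept update* — offset fit re-estimates only the intercept.
2. *Logistic calibration* — `logit P(y=1) = b₀ + b₁·LP`; the update is
   composed into the equation (coefficients scaled by b̂₁, intercept
   b̂₀ + b̂₁·β₀) so the updated model is immediately usable. Both levels are
   monotone in LP, so discrimination is provably unchanged.
3. *Full refit* — every coefficient re-estimated by ridge-penalised
   logistic regression on the template's predictor set, with an optional
   predictor swap (country of birth for ethnicity) for codings that do not
   transport. Ridge rather than LASSO because the predictor set is
   forced-entry (no selection is wanted) and a ~15-event cohort needs
   shrinkage, not sparsity. The penalty is chosen by outcome-stratified,
   seeded 5-fold cross-validation over λ ∈ 10^{−3..3} unless fixed.
   Standard errors come from the inverse penalised Hessian at the solution
   (X'WX + λI, intercept unpenalised) — approximate, but adequate for the
   coefficient-recovery checks they serve. When events number fewer than
   predictors the fit proceeds under shrinkage with a logged warning,
   mirroring the realistic small-validation-cohort situation.

## Decision curve analysis

Net benefit `NB(t) = TP/n − (FP/n)·t/(1−t)` with risk ≥ t (inclusive)
defining "intervene"; treat-all follows the closed form
`π − (1−π)·t/(1−t)` and treat-none is identically zero. The default grid
is 0.01–0.30 in steps of 0.01: above roughly a one-in-three chance,
intervention would not plausibly be withheld, so larger thresholds carry no
decision content. Bootstrap bands resample participants once per replicate
(stratified) and evaluate the whole grid on that resample, so the band is
coherent across thresholds instead of pointwise-jagged. A net-benefit
difference Δ over a comparator is reported as Δ·100 additional true
positives per 100 people at no increase in false positives, and as Δ/π of
all cases.

## Missing data

Chained-equation imputation is delegated to statsmodels' `MICEData`
(predictive-mean matching, k = 5 donors), wrapped to run m independent
chains, each seeded from one master seed and burnt in for a fixed number of
sweeps. PMM keeps imputed biochemistry inside the observed range and
returns observed 0/1 values for binary columns. Defaults m = 10,
10 sweeps; the pipeline uses 5 sweeps, which the trace behaviour of these
low-dimensional imputation models comfortably supports. The imputation
model includes the outcome and all analysis predictors (congeniality).
Scalar estimates are pooled by Rubin's rules (total variance
W̄ + (1+1/m)·B) with t-based intervals on the classical Rubin df, or
Barnard–Rubin-adjusted df when a complete-data df is supplied. Bounded
statistics (C-statistic, proportions) are pooled on the logit scale with
delta-method variances and back-transformed intervals so small-sample
pooling cannot leave (0, 1). Plot-shaped outputs are computed in every
imputed dataset and one seeded representative is presented.

## Synthetic cohort generator

The generator emulates the published validation sample's *marginals*:
n = 116; age truncated-normal on [16, 35] whose realised mean is 20.1
(SD 3.2); 73% male; 67% born in Australia; 35% smokers; 84% on
higher-metabolic-activity antipsychotics; follow-up times Beta-shaped,
right-skewed, rescaled into [1, 6] years with mean 2.6; target incident
MetS prevalence 13%.

Baseline biomarkers are drawn through a Gaussian copula (BMI, waist, HDL,
triglycerides — log-normal, right-skewed — SBP, glucose) with modest
positive correlations among adiposity, lipids, pressure and glucose, and
diastolic pressure is systolic minus an independent pulse pressure so
DBP < SBP by construction. **The joint structure is fictional**: published
sample descriptions determine marginals only, so the default correlations
are a once-chosen plausible guess, and nothing downstream should be read as
evidence about the real joint distribution. Baseline panels are redrawn
until IDF-negative, so generated records pass the eligibility filter by
construction (a `plant_violations` option inserts deliberate failures for
eligibility tests).

True risk is `invlogit(s·LP + δ + c)` where LP is the truth model's linear
predictor, `(δ, s)` an optional planted calibration drift, and `c` an
intercept offset solved by bisection so the mean true risk hits the target
prevalence (skipped when no target is set, e.g. in self-consistency tests
where the truth must equal the model exactly). Outcomes are Bernoulli draws
of the true risk; follow-up panels are rejection-sampled conditional on the
drawn outcome (cases from adversely shifted progression distributions,
non-cases from mild drift), so the IDF classifier reproduces the drawn
labels exactly. If an extreme baseline keeps failing, the progression means
are nudged further in the conditioning direction every 50 attempts — a
deliberate trade of tail fidelity for guaranteed termination. Analysis-
stage missingness defaults to 20% MCAR holes in HDL and triglycerides,
mirroring the considerable missingness of blood results in routine audit
data; MAR with a logistic dependence on an observed driver is available.

What passing tests therefore show: the *procedures* are correct (metrics
match oracles, planted drifts are recovered, known coefficients are
re-estimated, imputation recovers complete-data means). What they do not
show: performance numbers on any real cohort, whose joint covariate
structure, missingness mechanism and measurement error the simulator does
not claim to reproduce.

## Pipeline

Stages run in fixed order — simulate/load, eligibility, missingness
injection (synthetic cohorts), chained-equation imputation, per-imputation
validation of each model, pooled logistic recalibration (b₀, b₁ pooled by
Rubin's rules, then composed once into the updated equation), pooled ridge
refit (coefficients pooled across imputations), re-validation, decision
curves. One master seed fans out to stage-specific seeds by hashing
`"{seed}:{stage label}"` (blake2s, 31-bit), so stages are independently
reproducible and a re-run byte-reproduces the report. Updating uses all
data, matching the whole-sample recalibration such small validation studies
perform; the re-validated updated-model performance is therefore apparent
(optimism-prone) by construction and labelled as such.

Problem sizes used by the test-suite and the acceptance script — n = 20000
for self-consistency and drift recovery, n = 5000 for coefficient and
imputation recovery, 50 repetitions for the imputation coverage check,
n = 116 / m = 10 for the study emulation — were chosen as the smallest
sizes at which the binomial/logistic sampling noise is comfortably inside
the stated tolerances.

## Known limitations

* Calibration standard errors for the refit are penalised-Hessian
  approximations; they ignore penalty-selection variability.
* The generator draws no longitudinal trajectory between baseline and
  follow-up and no drug switching; follow-up biochemistry is conditioned
  only on the binary outcome.
* Rubin pooling of the calibration slope uses analytic (observed-
  information) within-imputation variances; with 15 events these are
  first-order approximations.
* The packaged reference coefficients are synthetic stand-ins; conclusions
  about the real algorithm require transcribing its published coefficient
  table into the template config.
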