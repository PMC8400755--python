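# Methods

This note documents the models, the synthetic data-generating process,
the numerical choices, and the places where the design was genuinely
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design and data model

The design is a quasi-experimental two-arm cohort: an integrated-care
programme arm (HCPC) and a usual-care arm (UC), each patient measured at
baseline (T0) and 6-month follow-up (T1) on a set of validated
instruments.  Cohort tables are long over patient × wave with a wide
outcome block and a wide block of 3-month resource-use counts; missing
values are empty fields.  Two cohort rules run before any modelling:

* patients with a follow-up record but no baseline record are removed
  (they cannot contribute a change anchored at baseline);
* sporadic missing outcome values are mean-imputed within
  arm × wave × outcome strata.  Mean imputation preserves every stratum
  mean exactly (asserted as a property test); a stratum with no observed
  value at all is an error, not a silent fill.  Missing covariate
  categories (living condition, smoking, education) are retained as
  explicit `missing` levels, mirroring how baseline tables report them,
  and are never imputed.

The imputation stratifies by wave as well as arm because the baseline and
follow-up distributions of most instruments differ; this is a documented
extension of the plain by-arm rule.

## Outcome set

Eight core outcomes span the Triple Aim: physical functioning (Katz-15
ADL, 0–15, higher = worse), psychological well-being (MHI-5, 0–100),
social relationships & participation (IPA social domain, 0–28, higher =
worse), enjoyment of life (ICECAP-O, 1–4), resilience (Brief Resilience
Scale, 6–30), person-centredness (P3CEQ, 0–18), continuity of care
(NCQ + CPCQ, 1–5) and total 3-month health and social care costs (NOK,
higher = worse).  Programme-specific additions for frail-elderly care:
autonomy (Pearlin Mastery Scale, 7–35), medication burden (LMQ, 0–10,
higher = worse) and informal-care costs (NOK, higher = worse).  Each
outcome's direction drives the sign annotation of effects and the
reciprocal transform in standardization.

## Synthetic cohort generator

The generator realises exactly the model the analysis assumes, so every
downstream estimand has a known truth:

* **Covariates.** Age ~ truncated normal (mean 81.5, SD 8.5, range
  65–100); sex, living condition, smoking, education and multi-morbidity
  (94% with ≥ 2 conditions) drawn from fixed categorical distributions
  typical of a frail elderly home-care population.
* **Outcomes.** Per outcome, patient mean = baseline mean + age slope ×
  (age − 81.5) + random intercept; waves add residual noise, a common
  time trend, and the treatment effect only in the programme arm at
  follow-up.  A single `baseline_sd` is split into intercept and residual
  components with an intraclass correlation of 0.6 (typical for repeated
  patient-reported measures) unless both components are given explicitly.
  Scores are clipped to their instrument bounds.  Cost outcomes replace
  the Gaussian intercept with a mean-preserving lognormal patient factor
  (their SD can exceed their mean), while trends and the treatment effect
  stay additive — so the configured effect remains the exact ATT truth
  even for skewed outcomes.
* **Assignment.** The arm is drawn from a logistic model on standardized
  age, sex and the *observed* baseline physical-functioning and
  social-participation scores (log-odds −0.50, −0.40, −0.35, +0.30 per
  SD), with the intercept solved by root-finding so the expected
  programme count equals `n_hcpc`.  Assigning on observed baselines makes
  the default propensity model correctly specified with respect to the
  assignment mechanism, which is the regime in which the recovery and
  coverage tests are meaningful.  Baseline arm differences (the programme
  arm younger, less male, less ADL-dependent, more participation-
  restricted) therefore emerge from confounding, not from a structural
  baseline arm term.
* **Observation process.** Arm-specific follow-up attrition
  (defaults 1 − 86/120 ≈ 0.283 and 1 − 41/89 ≈ 0.539, reproducing the
  evaluated cohort's follow-up sizes), 2% sporadic item missingness, and
  four injected follow-up-only respondents for the cohort rules to
  remove.  Attrition is covariate-independent by default; outcome-
  dependent mechanisms can be emulated by configuring per-arm
  probabilities externally, but are not a generator feature.
* **Defaults.** Baseline means/SDs, time trends and treatment effects
  follow the evaluated study's observed baselines, usual-care changes and
  estimated differences in change (e.g. resilience +2.08, autonomy
  −2.92, total costs −29,550 NOK), so the default cohort reproduces that
  effect-size regime.  One seeded generator drives all draws; a given
  seed yields a byte-identical cohort.

What the generator does **not** emulate: informative attrition, proxy
respondents, measurement error correlated across instruments, floor/
ceiling clumping beyond simple clipping, and municipality-level
clustering.  Passing tests therefore demonstrate that the estimators
recover the truth under the assumed model, not that the assumptions hold
in any real cohort.

## Propensity weighting and balance

Logit propensity on the default covariate set; categorical covariates
enter as indicator sets with the most frequent level as reference, and
levels observed fewer than 5 times are folded into the reference to keep
the Hessian well conditioned.  Newton is tried first; under
quasi-separation (common at n ≈ 200 with rare levels) the fit falls back
to BFGS.  Fitted propensities are truncated to [0.01, 0.99] with a logged
count before weighting — untruncated ATT weights can explode in small
samples.  Weighted moments use frequency-normalized weights
(weights scaled to sum to the sample size; variance denominator
Σw − 1), and significance of standardized differences uses a weighted
Welch test on effective sample sizes (Σw)²/Σw².  Rubin's B and R are
computed on the propensity linear index, unweighted and ATT-weighted,
with pass thresholds B < 25 and 0.5 < R < 2.

## Weighted random-intercept model

statsmodels' mixed-model implementation does not accept observation
weights, so the weighted maximum likelihood is implemented in the
package: ATT weights are patient-level probability weights multiplying
each patient's marginal log-likelihood contribution, the marginal
covariance of a patient's residual vector is σψ²J + σε²I (1×1 or 2×2
blocks, evaluated in closed form and vectorized), the fixed effects are
profiled out by GLS, and the two variance components are optimised by
Nelder-Mead on the log scale (xatol 1e-10, started from an equal split
of the total variance).  Inference uses a cluster-robust sandwich over
patients.  At unit weights the implementation agrees with statsmodels'
ML mixed model to the displayed precision (coefficients, variance
components, log-likelihood) — that cross-check is a test, and the two
routes are never collapsed.  Estimation is ML, not REML, so fixed-effect
comparisons across outcomes are consistent.

Patients lost to follow-up contribute their baseline row.  Outcomes are
modelled as continuous regardless of scale, for ease of interpretation;
bounded scales are therefore approximated near their bounds, which is
visible as a small attenuation of recovered effects for outcomes whose
trajectories approach a bound (the recovery study uses resilience, whose
configured trajectory stays ~2 SD from its bounds).

Predictions: the programme arm's follow-up mean is evaluated at I=1,
T=1 and the programme arm's mean age at follow-up; the usual-care
counterfactual subtracts β3 (additive re-anchoring), so both predictions
share the programme baseline anchor and differ by β3 exactly.  Arm
changes reported in the effects table are β2 (+ age drift over the
half-year between waves) and β2 + β3.

## Costing

Components are count × unit provider cost × CPI factor.  Tariff-based
services (GP, physiotherapist, specialist, outpatient visits) are
grossed up to provider cost by dividing by (1 − co-payment share): with
co-payments stated as a share *of* provider cost, the tariff understates
the provider cost, so the gross-up direction follows.  The GP fee is the
specialist-share-weighted average of NOK 165 and NOK 257; the specialist
share is not published, so it defaults to 0.5 and is configurable.
Hospital days use the NOK 8,400 per-diem; informal care hours are valued
at the home-care unit cost (default NOK 450/h — municipal price lists
are not published, so this is a configurable stand-in).  Medication is a
single per-patient defined-daily-dose component rather than a per-ATC
lookup.  Missing counts are costed as zero with a logged warning.  CPI
inflation is applied uniformly across components.  EUR equivalents
divide by 9.8527 (2019 average).

## Standardization and value scores

Relative standardization maps an outcome's arm pair to the unit circle;
reverse-coded outcomes are reciprocal-transformed first, so a higher
standardized score always means better performance and
S_a² + S_b² = 1 holds by construction.  The transform requires strictly
positive inputs; raw performance values at or below zero (possible for
zero-anchored scales after prediction) are shifted by a configurable
+1 in both arms, with a loud log message — the reciprocal rule is
undefined at zero and the choice of shift is a documented convention,
not a published rule.  Standardization is invariant to common positive
rescaling of both arms (so the currency of cost outcomes is
irrelevant).  Stakeholder weights are applied exactly as given, without
renormalization: published weight columns sum only approximately to 1,
and the published overall scores are reproduced under as-given weights.
Reports round half-to-even at 3 decimals; internal computation is full
precision.

Reproduction of the published value table starts from its printed
standardized scores (the raw predicted values behind them were not
printed).  Because those inputs are themselves rounded to 3 decimals,
two stakeholder columns re-aggregate to values 0.001–0.002 away from the
printed overalls; the tests treat five cells as exact at 3 decimals and
the rest within ±0.002.

## Sensitivity analysis

Score uncertainty: per outcome, a 2×2 covariance from the prediction
standard errors and the between-arm covariance (both predictions share
most coefficients, so they are strongly positively correlated);
outcomes are independent blocks unless a full covariance is supplied.
Weight uncertainty defaults to none and can be supplied as per-outcome
standard errors or full covariances; weight and score blocks are
sampled independently of each other (the joint covariance between
preferences and performance is not identified by any published
quantity).  Draws are mean + Lz with L the Cholesky factor; numerically
indefinite covariances are repaired by eigenvalue flooring with a
logged count.  Negative weight draws are truncated at zero (logged);
score draws violating positivity are resampled within a bounded retry
budget (error if the budget is exhausted — that indicates means within
noise of zero, where the ratio standardization is not meaningful).
Intervals are equal-tailed percentiles of the replication distribution.
With all covariances zero the Monte Carlo path reproduces the
deterministic value scores bit-for-bit: the scalar and vectorized
standardizations use the same operation order, and degenerate
replication distributions short-circuit the mean/quantile step.

Swing-weight sensitivity is the same deterministic aggregation under an
alternative weight source, optionally over the extended outcome set
(core + autonomy, medication burden, informal-care costs); the swing
weight values themselves are user inputs.

## Problem sizes and tolerances

The balance acceptance check uses 2,000 patients per arm (large enough
that residual standardized bias under a correctly specified model is a
few percent).  The recovery/coverage study uses 200 study-sized cohorts
(120/89 with default attrition) in the test suite and 100 in the
acceptance script; with robust CIs the Monte Carlo error of a coverage
estimate at 200 replicates is about ±1.5 points, hence the [90, 98]
acceptance band around the nominal 95.  Monte Carlo sensitivity
analyses use the full 10,000 replications.  Closed-form identities
(DiD equals the four-cell-mean contrast; prediction gap equals β3) are
asserted at 1e-8 and 1e-12 respectively.

## Known limitations

* Continuous-outcome models on bounded scales; no ordinal or
  generalized linear mixed models.
* Single mean imputation only — no multiple imputation; uncertainty from
  imputation is not propagated.
* The propensity model's estimation uncertainty is not propagated into
  the effect-model standard errors (robust SEs condition on the
  weights), the usual practice in this design and typically
  conservative.
* ATT weights only; no ATE, overlap weights or matching.
* The sensitivity analysis treats preference weights and performance
  scores as independent blocks.
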