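# Methods

`dietcal` implements the statistical pipeline of a diet–mortality cohort
analysis in a population with very low meat intake, together with a
synthetic cohort generator used to validate every stage. This note
documents the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic validation does and does not establish.

## 1. Exposure assessment

Food-frequency questionnaire (FFQ) responses are categorical: a frequency
level ("never or rarely" … "2+ per day") and a serving size (half,
standard, one-and-a-half). The product-sum method converts them to grams
per day:

    intake = frequency weight (times/day) × serving multiplier × serving grams,

summed over the items of a food group. Unprocessed red meat comprises the
two beef/lamb items; processed meat comprises processed beef/lamb,
processed poultry, and pork (the pork item is dominated by processed
products); the combined exposure is their sum. Exact frequency weights
differ by instrument, so the shipped default maps the
nine-level scale to {0, 1/30, 2.5/30, 1/7, 2.5/7, 5.5/7, 1, 1.5, 2.5}
times/day and the standard meat serving to 99 g (midpoint of the 3–4 oz,
85–113 g range); both live in configuration (`WeightMap`), not code.

**Energy adjustment** uses the residual method: OLS of intake on total
energy, adjusted value = residual + mean intake. The adjusted column is
exactly uncorrelated with energy, mean-preserving, and the operation is
idempotent; a constant energy column is rejected. For the continuous Cox
term, adjustment is applied on the model (transformed) scale so the
contrast stays linear in the coefficient; quartile cut points use the
adjusted raw-scale values with the zero-intake group pinned by raw
intake = 0 (energy adjustment perturbs zeros off 0).

**Exclusions** (missing dietary data, energy <500 or >4500 kcal/day with
strict inequalities, missing age/sex/race, age <25, prevalent
cancer/CVD) are applied sequentially in that order, each row counted once
under the first matching rule; the ledger makes the attribution auditable
because per-category exclusion counts can overlap.

**Categorization** forms a zero-intake level plus quartiles of consumers
(default). A `quartile_basis="total"` switch computes cut points over the
whole cohort instead, but with ~65% zero consumption those quantiles
collapse to zero and the call fails loudly — the reason consumers is the
default.

## 2. Survival model

The hazard model is Cox proportional hazards on the **attained-age time
scale with left truncation**: a subject enters the risk set at their study
entry age and leaves at death or censoring age, so the risk set at event
age t is {i : entry_i < t ≤ exit_i}. All covariates are fixed at baseline.
Deaths from unnatural causes (ICD-10 letters U, V, W, X, Y) are censoring
events for every outcome, including all-cause; for cause-specific outcomes
(CVD = I00–I78, cancer = C00–C97) deaths from other causes are censored at
the death age.

The partial likelihood is maximized by Newton–Raphson with step-halving.
Tied event ages use Efron's approximation by default (Breslow selectable);
the synthetic ages are continuous so ties effectively never occur there,
but the Efron path is exercised against a reference implementation on
coarse times. Risk-set sums are computed in O(n log n + m p²) with two
suffix accumulators (exit-ordered and entry-ordered) evaluated at the m
distinct event ages; the p×p outer-product sums use per-segment BLAS
products rather than a full-length cumulative array.

Numerical decisions:

- Covariates are centered before optimization (coefficients are
  shift-invariant; conditioning improves).
- Convergence: score infinity-norm < 1e-8, or Newton step < 1e-9·(1+|β|).
  The step criterion matters at n ≳ 10⁴, where accumulated floating-point
  error puts a ~1e-5 noise floor under the score; the step bound still
  limits the coefficient error to ~1e-9.
- Separation is declared when any |β|·sd(x) exceeds 10 (a hazard ratio of
  e¹⁰ per covariate SD), either mid-iteration or at a vanished score.
- The covariance is the inverse observed information, symmetrized.

**Contrasts.** Continuous intakes enter the model through a transform g;
the headline contrast compares the 90th percentile of intake with zero,
HR = exp(β·(g(x₉₀) − g(0))). Log-transforming a right-skewed intake is
standard, but a pure log cannot represent the zero-intake reference; the
default here is g(x) = log(1+x) so g(0) = 0 is defined, with `log_offset(c)` and identity
available in configuration for side-by-side comparison.

**Trend test.** Each subject is assigned the median intake of their
five-level category (0 for the zero-intake level, since the zero group's
median raw intake is 0) and the score is analyzed as a continuous
variable; the Wald p of its coefficient is the trend p.

**Splines.** Linearity is assessed with 4-knot restricted cubic splines
(truncated-power natural-spline basis, linear beyond the boundary knots,
normalized by the squared knot span), knots at the 5/35/65/95 percentiles —
the standard placement — configurable. The nonlinearity test is the joint
Wald test that the K−2 nonlinear coefficients vanish.

**Proportional-hazards diagnostics.** Scaled-Schoenfeld test in the
Grambsch–Therneau form (score statistic correlating per-event Schoenfeld
residuals with event age), an exact time-dependent refit with a
term × log(attained age) product (evaluated risk set by risk set, since no
cumulative trick applies to a time-varying covariate), and log(−log)
survival curves emitted as plot data for visual inspection only.

**Interactions.** Wald (default) or likelihood-ratio test of the product
term; the two agree to first order and a test asserts it at large n.

## 3. Measurement-error correction

Dietary self-report carries classical error that attenuates hazard ratios
toward the null by roughly the reliability λ. The correction is
regression calibration: in a substudy with six 24-h recall replicates,
regress the recall-mean intake on the FFQ intake plus the analytic
covariates of the model being calibrated; the predicted recall intake
replaces the FFQ exposure in the Cox model. Only the exposures are
calibrated, never the covariates.

Two scale decisions:

- Calibration operates on the **model scale** (default log1p of g/day) —
  the error-prone quantity entering the hazard model is the one being
  calibrated. Regression calibration is often written on the raw intake
  scale; on the transformed scale the classical-error algebra (slope = λ, calibrated
  β ≈ naive β / λ) is exact under the generator, which is what the
  recovery tests verify.
- The calibrated variable lives on the reference-instrument (recall)
  intake scale, so the 90th-vs-0 contrast applies directly to its
  coefficient: HR_cal = exp(β_cal·(g(x₉₀) − g(0))). Because β_cal ≈
  β_naive/λ, a slope below 1 widens the contrast — the calibrated >
  uncalibrated pattern classical error predicts.

**BCa bootstrap.** Confidence intervals for calibrated hazard ratios come
from a bias-corrected and accelerated bootstrap (default B = 4000; the
validation studies run scaled-down B) that resamples cohort and substudy
subjects independently and refits the calibration model in every
replicate, so the interval reflects calibration-stage uncertainty
(`bootstrap="fix_calibration"` disables the refit). z₀ is the normal
quantile of the fraction of replicates below the point estimate (clipped
to (1/(B+1), B/(B+1))); the acceleration a is the jackknife skewness of
leave-one-unit-out estimates. Above 2000 units per table, contiguous
delete-block jackknife (200 blocks) replaces leave-one-out — the
acceleration ratio is block-size invariant for iid rows, and 20,000 Cox
refits are not a price worth paying for it. With z₀ = a = 0 the interval
reduces exactly to the percentile interval. Replicates that fail to refit
are dropped and counted; more than 5% failures aborts. The pipeline
computes the BCa interval at a fixed (first) imputed dataset; there is no
single standard for combining bootstrap intervals with multiple
imputation, and doing so jointly is out of scope.

**Deattenuation.** The FFQ validity correlation corrects the FFQ–recall
correlation for within-person recall noise: r_true = r_obs·√(1 + λ/k),
with λ the within/between-person variance ratio from one-way ANOVA
components of the k replicates, computed on the log1p scale among
consumers (zeros are exact on both instruments by construction and would
inflate the correlation). Values pushed past |1| are clipped with a
warning; non-positive between-person variance is an error.

## 4. Missing data

Chained-equations multiple imputation, m = 5 by default: continuous
covariates by predictive-mean matching (5 donors, parameter uncertainty
via a bootstrap refit of the imputation model per imputation), categorical
covariates by multinomial-logistic draws, five sweeps, deterministic given
the seed. Exposure and outcome columns are never imputed; a column over
50% missing warns, an all-missing column fails. Pooling follows Rubin's
rules: pooled β = mean, T = W + (1 + 1/m)·B, degrees of freedom
ν = (m−1)(1 + W/((1+1/m)B))², t-based intervals, pooling on the log-HR
scale. The women-only menopause covariate is structurally missing for men
and is excluded from imputation by default.

## 5. Analysis grid and derived quantities

`run_full_analysis` crosses {unprocessed red, processed, combined} ×
{all-cause, CVD, cancer} × {model 1, 2, 3}. Model 1 adjusts for age (the
time scale), sex, race and energy; model 2 adds lifestyle, medical and
dietary covariates; model 3 adds the other meat groups — except for the
combined exposure, which is never mutually adjusted for its own
components. Cancer cells add a screening covariate from tier 2 up. Each
cell reports Rubin-pooled quartile HRs, trend p, and 90th-vs-0 contrasts
uncalibrated and calibrated; a failed cell is recorded with a
machine-readable reason and the rest of the grid proceeds. Subgroup
analyses by sex and race refit per stratum with stratum-specific 90th
percentiles and attach the interaction p; strata under 30 events are
flagged low-information, not dropped. The never-smoker sensitivity
analysis filters to the "never smoked" level and reruns the grid without
the smoking covariate.

**Population attributable risk** uses Levin's formula,
PAR = p(HR−1)/(1 + p(HR−1)), with p the fraction of the cohort at or
above the 90th-percentile exposure — a deliberate, logged choice among
the several attributable-fraction definitions in use; a causal reading of the HR is
assumed.

## 6. The synthetic cohort generator

The generator is first-class, tested code. It emulates:

- **Exposures**: a Gaussian copula on latent normals; a subject consumes
  food g iff its latent exceeds the zero-inflation threshold (defaults
  0.646 red, 0.667 processed, matching the zero-intake fractions), and
  consumer intake is the conditional-quantile remap to LogNormal(μ, σ)
  (red μ=2.3, σ=1.1; processed μ=0.75, σ=1.3 — chosen to approximate the
  consumer quartile medians of roughly 4/9/16/42 and 0.7/1.4/3/9 g/day,
  which no lognormal fits exactly).
  The latent correlation is calibrated by bisection against an exact
  2-D Gauss–Hermite computation of the observed intake correlation so the
  realized Pearson r hits the target (default 0.56).
- **Measurement**: classical error on the log1p scale, FFQ =
  expm1(log1p(true) + ε); default error SDs give validity correlations
  0.74 (red) and 0.43 (processed). Perturbed values are floored at 0
  (reported intakes cannot be negative), slightly truncating the error's
  left tail for low-intake consumers; true zeros report zero on every
  instrument. The substudy (default 1000 subjects, equal Black/non-Black
  allocation) gets six recall replicates with independent within-person
  error.
- **Survival**: Weibull baseline on the age scale (shape 9, scale 92 —
  calibrated at design time to ~11% deaths over a mean ~11.8-year
  follow-up with accrual ages 25–90 centered at 56), log-linear hazard in
  the configured true effects, inverse-transform sampling conditional on
  survival to the entry age (the closed form is the KS-test oracle).
  Causes are drawn from a configurable mixture and emitted as ICD-10-like
  strings so the analysis-side classifier is genuinely exercised.
- **Missingness**: MAR driven by observed sex and entry age, rescaled to
  hit the target marginal rate.

One global seed feeds a fixed `SeedSequence` stream split (exposures,
covariates, ffq, recalls, survival, missingness, substudy), so identical
configs give byte-identical tables.

What the generator does **not** emulate: item-level questionnaire
structure beyond one demonstration mapping, nutrient composition,
diet–covariate dependence beyond an optional smoking–meat confounding
knob, time-varying diet, competing-risks structure beyond the categorical
cause label, and real-data quirks (digit preference, differential
reporting by adiposity, correlated recall errors). Passing recovery tests
therefore establishes internal statistical correctness of the estimators
under classical-error and MAR assumptions — not that those assumptions
hold in any real cohort.

## 7. Validation scale

The validation studies are sized to run on one CPU in minutes, as the
package's own test-design choice: attenuation/calibration recovery at
n = 20,000 with a 1,000-subject substudy over 200 replicates; BCa coverage
over 500 simulations at B = 2,000; Rubin-pooled CI coverage over 500 MAR
simulations; type-I-error calibration of the Wald, trend, interaction,
Schoenfeld and spline tests over 500 null simulations at n = 800; validity
recovery over 20 replicates. The demonstration analyses under `analysis/`
use a 12,000-subject cohort with B = 200. The full-scale settings
(B = 4000, m = 5) remain the library defaults.

## 8. Known limitations

- Regression calibration assumes nondifferential classical error and a
  linear calibration model; the two-stage Wald CI for the calibrated HR
  ignores calibration-stage uncertainty (the BCa interval is the honest
  one).
- The trend test inherits the arbitrariness of category medians under
  heavy zero inflation.
- The age-interaction PH check evaluates the full risk set at every event
  age (O(m·n)); it is meant for diagnostics, not bulk fitting.
- `total`-basis quartiles fail under majority-zero exposures by design.
- PAR is reported under Levin's formula only; alternative counterfactual
  PAF definitions give different numbers.
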