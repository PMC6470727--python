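# dietcal

Statistical pipeline for diet–mortality cohort analyses in low meat-intake
populations: from categorical food-frequency questionnaire (FFQ) responses
to regression-calibrated, multiply-imputed hazard ratios.

Cohorts with many zero consumers let an analysis compare *low-to-moderate*
meat intake against *zero* intake — a contrast most studies cannot form.
Doing that defensibly requires machinery that rarely lives in one place:

- **FFQ intake processing** — product-sum g/day conversion
  (frequency weight × serving multiplier × serving grams), food-group
  aggregation (unprocessed red, processed incl. pork, combined), residual-
  method energy adjustment, auditable exclusion filters, and a zero-intake
  + consumer-quartile categorization.
- **Survival engine** — Cox proportional hazards on the attained-age time
  scale with left truncation (risk set at age t: entry < t ≤ exit),
  Efron/Breslow ties, ICD-10 cause classification with unnatural-death
  censoring, 90th-percentile-vs-zero contrasts
  HR = exp(β·(g(x₉₀) − g(0))) with g = log(1+x), quartile-median trend
  tests, 4-knot restricted cubic spline nonlinearity tests,
  scaled-Schoenfeld and age-interaction proportional-hazards diagnostics,
  and effect-modification tests.
- **Measurement-error correction** — regression calibration against a
  replicate 24-h recall substudy (calibrated β ≈ naive β/λ under classical
  error with reliability λ), BCa bootstrap intervals (bias-correction z₀,
  jackknife acceleration a) resampling cohort and substudy independently,
  and ANOVA-based deattenuated validity correlations
  r_true = r_obs·√(1 + λ/k).
- **Missing data** — chained-equations multiple imputation (PMM for
  continuous, multinomial draws for categorical) with Rubin pooling,
  T = W + (1 + 1/m)·B.
- **Orchestration** — the exposure × outcome × covariate-tier grid,
  subgroup and never-smoker sensitivity analyses, Levin's population
  attributable risk PAR = p(HR−1)/(1 + p(HR−1)), and descriptive baseline
  tables.
- **Synthetic cohorts** — a generator with ground truth: Gaussian-copula
  zero-inflated lognormal exposures with a calibrated cross-food
  correlation, classical FFQ/recall error with configurable validity,
  conditional Weibull survival on the age scale, cause codes, and MAR
  covariate missingness. Every estimator above is validated against it.

The Cox engine, BCa bootstrap, calibration, deattenuation, imputation and
pooling are implemented here and cross-checked against independent oracles
(brute-force likelihood maximization, a reference survival library,
closed-form identities, coverage simulations) in the test suite.

## Worked example

```python
import numpy as np
from dietcal import (SimulationConfig, generate_dataset, fit_cox,
                     contrast_hr, calibrated_hazard_ratio, event_indicator)

cfg = SimulationConfig(
    n_subjects=20000, seed=1,
    true_log_hr={"combined_red_processed": np.log(1.5) / np.log1p(49.1)},
)
cohort, substudy, truth, _ = generate_dataset(cfg)
cohort["event"] = event_indicator(cohort["death"].to_numpy(),
                                  cohort["cause_code"], "all_cause")
cohort["x"] = np.log1p(cohort["ffq_combined_red_processed"])
x90 = float(np.quantile(cohort["ffq_combined_red_processed"], 0.9))

naive = contrast_hr(fit_cox(cohort, ["x"]), "x", x90, 0.0)
cal, _, model = calibrated_hazard_ratio(cohort, substudy,
                                        "combined_red_processed", [], x1=x90)
print(f"90th-vs-0 contrast at {x90:.1f} g/day")
print(f"  uncalibrated HR {naive.hr:.2f} ({naive.ci_low:.2f}-{naive.ci_high:.2f})")
print(f"  calibrated   HR {cal.hr:.2f} ({cal.ci_low:.2f}-{cal.ci_high:.2f})")
```

```
90th-vs-0 contrast at 38.1 g/day
  uncalibrated HR 1.39 (1.28-1.52)
  calibrated   HR 1.54 (1.38-1.72)
```

The true simulated contrast is HR 1.5. FFQ measurement error attenuates
the naive estimate toward 1; regression calibration against the recall
substudy restores it (with a wider, honest interval). This
calibrated-greater-than-uncalibrated pattern is the signature of classical
exposure error.

## Analysis scripts

Numbered drivers under `analysis/` run the full study on a simulated
12,000-subject cohort and write tables under `results/`:

| script | what it does |
|---|---|
| `01_simulate_cohort.py` | generate cohort, recall substudy, ground truth |
| `02_process_intake.py` | categorical FFQ → g/day, exclusions, energy adjustment, categories |
| `03_fit_mortality_models.py` | the exposure × outcome × model grid with imputation and calibration |
| `04_measurement_error.py` | validity/deattenuation and calibration slopes per food group |
| `05_subgroups_sensitivity_par.py` | sex/race subgroups, never-smoker rerun, PH diagnostics, PAR |

A thin CLI wraps the same library: `dietcal simulate`, `dietcal intake`,
`dietcal calibrate`, `dietcal run`.

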