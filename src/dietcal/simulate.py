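"""Synthetic cohort generator.

Emulates the data structure of a large North-American church-member cohort
with very low meat intake: zero-inflated, right-skewed meat exposures that
are correlated across food groups; a food-frequency questionnaire (FFQ)
measurement with classical error; a calibration substudy with replicate
24-h recalls; left-truncated survival on the attained-age scale with
cause-specific ICD-10-like death codes; and missing covariate cells under a
MAR mechanism.

Exposure joint distribution: a Gaussian copula on latent normals. Subject i
consumes food g iff the latent Z_ig exceeds the zero-inflation threshold;
consumers' intake is the conditional-quantile remap
exp(mu + sigma * Phi^{-1}((Phi(Z) - p0) / (1 - p0))), which makes consumer
intakes exactly LogNormal(mu, sigma) while the shared latents carry the
cross-food correlation. The latent correlation is calibrated numerically so
the *observed* Pearson correlation between the two meat intakes hits the
configured target.

Measurement error is classical on the log1p scale (the scale on which the
analysis models intake): FFQ = expm1(log1p(true) + e_f), recall replicate
j = expm1(log1p(true) + e_wj), with true-zero subjects reporting zero on
every instrument.

Randomness: one global seed feeds a documented SeedSequence stream split —
child streams, in order: exposures, covariates, ffq, recalls, survival,
missingness, substudy selection. Identical configs give byte-identical
output tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoodDistribution",
    "SimulationConfig",
    "generate_true_exposures",
    "generate_ffq_and_recalls",
    "generate_survival",
    "inject_missingness",
    "generate_dataset",
    "write_dataset",
    "ffq_sd_for_validity",
    "latent_correlation_for_target",
]

FOODS = ["unprocessed_red", "processed", "poultry", "fish"]

SMOKING_LEVELS = [
    "never",
    "quit_30plus",
    "quit_20_29",
    "quit_10_19",
    "quit_5_9",
    "quit_1_4",
    "quit_lt1",
    "current",
]

CAUSE_CODES = {
    "cvd": ["I21", "I25", "I50", "I63", "I64", "I70"],
    "cancer": ["C18", "C34", "C50", "C61", "C25", "C97"],
    "other_natural": ["J18", "E11", "G30", "N18", "K74"],
    "unnatural": ["V43", "W19", "X42", "Y09", "U09"],
}


@dataclass
class FoodDistribution:
    """Zero-inflated lognormal marginal for one food group (g/day)."""

    zero_prob: float
    mu: float
    sigma: float

    def validate(self, name: str):
        if not 0.0 <= self.zero_prob < 1.0:
            raise ValueError(f"{name}: zero_prob must be in [0, 1)")
        if self.sigma <= 0:
            raise ValueError(f"{name}: sigma must be > 0")


def _default_exposures() -> dict:
    # zero fractions and lognormal shapes chosen to approximate the cohort's
    # zero-intake counts and consumer quartile medians (red: ~4/9/16/42 g/day,
    # processed: ~0.7/1.4/3.3/9.4 g/day)
    return {
        "unprocessed_red": FoodDistribution(0.646, 2.3, 1.1),
        "processed": FoodDistribution(0.667, 0.75, 1.3),
        "poultry": FoodDistribution(0.50, 2.6, 1.0),
        "fish": FoodDistribution(0.45, 2.5, 0.9),
    }


def log1p_scale_sd(dist: "FoodDistribution") -> float:
    """SD of log1p(intake) among consumers, by Gauss-Hermite quadrature."""
    from numpy.polynomial.hermite_e import hermegauss

    x, w = hermegauss(200)
    w = w / np.sqrt(2 * np.pi)
    y = np.log1p(np.exp(dist.mu + dist.sigma * x))
    m = float((w * y).sum())
    return float(np.sqrt((w * (y - m) ** 2).sum()))


def ffq_sd_for_validity(sigma: float, r: float) -> float:
    """Classical-error SD giving FFQ-truth correlation r on the error scale.

    corr(T + e, T) = sigma / sqrt(sigma^2 + sd_e^2) = r, with sigma the SD
    of the true signal on the scale the error is applied to (log1p here;
    use :func:`log1p_scale_sd` for a consumer marginal).
    """
    if not 0 < r <= 1:
        raise ValueError("validity correlation must be in (0, 1]")
    return sigma * np.sqrt(1.0 / r**2 - 1.0)


@dataclass
class SimulationConfig:
    """All the knobs of the synthetic cohort, with study-like defaults."""

    n_subjects: int = 20000
    seed: int = 0
    # hazard: keys are food names (coefficient per unit log1p(g/day)),
    # numeric covariate names (per unit), or "col=level" indicator terms
    true_log_hr: dict = field(default_factory=dict)
    weibull_shape: float = 9.0
    weibull_scale: float = 92.0
    # alternative baseline: piecewise-exponential on the age grid below
    # (rates default to the Weibull hazard at interval midpoints)
    baseline: str = "weibull"  # or "piecewise_exponential"
    piecewise_knots: tuple = (25.0, 45.0, 55.0, 65.0, 75.0, 85.0, 95.0, 110.0)
    piecewise_rates: tuple | None = None
    accrual_age_range: tuple = (25.0, 90.0)
    accrual_age_mean: float = 56.0
    accrual_age_sd: float = 14.0
    admin_censor_age: float = 110.0
    followup_years: float = 11.8
    followup_spread: float = 2.5  # uniform half-width around followup_years
    exposure_distribution: dict = field(default_factory=_default_exposures)
    exposure_correlation: float = 0.56  # observed Pearson r, red vs processed
    ffq_error: dict | float = field(
        default_factory=lambda: {
            # classical log1p-scale SDs giving validity 0.74 (red) / 0.43
            # (processed) against the consumer log1p-scale SD of the
            # marginals above (0.65 for poultry/fish)
            "unprocessed_red": 0.874,
            "processed": 1.798,
            "poultry": 1.058,
            "fish": 0.949,
        }
    )
    recall_error: dict | float = 0.5  # within-person SD of a single recall
    n_recalls: int = 6
    substudy_size: int = 1000
    cause_mixture: dict = field(
        default_factory=lambda: {
            "cvd": 0.33,
            "cancer": 0.24,
            "other_natural": 0.40,
            "unnatural": 0.03,
        }
    )
    missing_rates: dict = field(
        default_factory=lambda: {"bmi": 0.04, "exercise": 0.05, "education": 0.03}
    )
    smoking_meat_confounding: float = 0.0  # tilts smoking toward high red-meat latents
    smoking_log_hr: float = 0.0  # extra hazard for current smokers

    def validate(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.substudy_size > self.n_subjects:
            raise ValueError("substudy_size must be <= n_subjects")
        if self.n_recalls < 2:
            raise ValueError("deattenuation needs >= 2 recall replicates")
        for name, d in self.exposure_distribution.items():
            d.validate(name)
        if abs(sum(self.cause_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("cause_mixture probabilities must sum to 1")
        for col, r in self.missing_rates.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missing rate for {col} outside [0, 1)")
        if self.baseline not in ("weibull", "piecewise_exponential"):
            raise ValueError(f"unknown baseline {self.baseline!r}")

    def ffq_sd(self, food: str) -> float:
        e = self.ffq_error
        return float(e[food]) if isinstance(e, dict) else float(e)

    def recall_sd(self, food: str) -> float:
        e = self.recall_error
        return float(e[food]) if isinstance(e, dict) else float(e)

    def streams(self):
        names = ["exposures", "covariates", "ffq", "recalls", "survival", "missingness", "substudy"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# Exposures
# ---------------------------------------------------------------------------


def _intake_from_latent(z: np.ndarray, dist: FoodDistribution) -> np.ndarray:
    """Zero below the threshold; conditional-quantile lognormal above."""
    p0 = dist.zero_prob
    u = stats.norm.cdf(z)
    out = np.zeros_like(z)
    consumer = u > p0
    if p0 < 1.0:
        uu = (u[consumer] - p0) / (1.0 - p0)
        uu = np.clip(uu, 1e-12, 1 - 1e-12)
        out[consumer] = np.exp(dist.mu + dist.sigma * stats.norm.ppf(uu))
    return out


def _observed_r(rho: float, da: FoodDistribution, db: FoodDistribution, nq: int = 160) -> float:
    """Population Pearson r of the two zero-inflated intakes at latent rho.

    Exact (to quadrature error) via tensor Gauss-Hermite integration of
    E[f(Z1) g(rho Z1 + sqrt(1-rho^2) Z2)] over the standard bivariate normal.
    """
    from numpy.polynomial.hermite_e import hermegauss

    z, w = hermegauss(nq)
    w = w / np.sqrt(2 * np.pi)
    fa = _intake_from_latent(z, da)
    fb = _intake_from_latent(z, db)
    Ea, Eb = w @ fa, w @ fb
    Va = w @ fa**2 - Ea**2
    Vb = w @ fb**2 - Eb**2
    s = np.sqrt(max(1.0 - rho**2, 0.0))
    Z2 = rho * z[:, None] + s * z[None, :]
    G = _intake_from_latent(Z2.ravel(), db).reshape(Z2.shape)
    Eab = w @ ((G @ w) * fa)
    return float((Eab - Ea * Eb) / np.sqrt(Va * Vb))


def latent_correlation_for_target(
    target_r: float, da: FoodDistribution, db: FoodDistribution
) -> float:
    """Latent Gaussian correlation whose observed intake Pearson r hits target.

    Solved by bisection, exploiting monotonicity of the observed correlation
    in the latent one. Raises if the target exceeds the maximum achievable
    under the configured zero-inflation and marginal shapes.
    """
    if target_r == 0.0:
        return 0.0
    sign = np.sign(target_r)
    hi = 0.9999
    r_max = _observed_r(sign * hi, da, db)
    if abs(target_r) > abs(r_max):
        raise ValueError(
            f"infeasible correlation target {target_r:+.3f}: with zero-inflation "
            f"{da.zero_prob:.3f}/{db.zero_prob:.3f} the achievable |r| is at most "
            f"{abs(r_max):.3f}"
        )
    lo = 0.0
    for _ in range(40):
        mid = (lo + hi) / 2.0
        if abs(_observed_r(sign * mid, da, db)) < abs(target_r):
            lo = mid
        else:
            hi = mid
    return sign * (lo + hi) / 2.0


def generate_true_exposures(config: SimulationConfig) -> pd.DataFrame:
    """Per-subject true usual intakes (g/day) plus baseline covariates."""
    config.validate()
    rngs = config.streams()
    rng = rngs["exposures"]
    n = config.n_subjects
    dists = config.exposure_distribution
    rho = latent_correlation_for_target(
        config.exposure_correlation, dists["unprocessed_red"], dists["processed"]
    )
    z_red = rng.standard_normal(n)
    z_proc = rho * z_red + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    latents = {"unprocessed_red": z_red, "processed": z_proc}
    for food in FOODS[2:]:
        if food in dists:
            # mild positive association with the shared meat latent
            latents[food] = 0.2 * z_red + np.sqrt(1 - 0.04) * rng.standard_normal(n)
    df = pd.DataFrame({"subject_id": np.arange(n)})
    for food, z in latents.items():
        df[f"true_{food}"] = _intake_from_latent(z, dists[food])

    crng = rngs["covariates"]
    a, b = config.accrual_age_range
    alpha = (a - config.accrual_age_mean) / config.accrual_age_sd
    beta_ = (b - config.accrual_age_mean) / config.accrual_age_sd
    df["entry_age"] = stats.truncnorm.rvs(
        alpha, beta_, loc=config.accrual_age_mean, scale=config.accrual_age_sd,
        size=n, random_state=crng,
    )
    df["sex"] = np.where(crng.random(n) < 0.65, "F", "M")
    df["race"] = np.where(crng.random(n) < 0.26, "Black", "non-Black")
    df["education"] = crng.choice(
        ["high_school", "some_college", "bachelor", "graduate"], size=n,
        p=[0.25, 0.35, 0.22, 0.18],
    )
    df["marital"] = np.where(crng.random(n) < 0.72, "married", "single")
    # smoking, optionally confounded with the red-meat latent
    base_p = np.array([0.75, 0.08, 0.05, 0.04, 0.02, 0.015, 0.005, 0.04])
    c = config.smoking_meat_confounding
    tilt = np.exp(c * z_red)
    probs = np.tile(base_p, (n, 1))
    heavy = np.arange(1, 8)  # every ever-smoking level tilts with meat
    probs[:, heavy] *= tilt[:, None]
    probs /= probs.sum(axis=1, keepdims=True)
    u = crng.random(n)
    cum = np.cumsum(probs, axis=1)
    df["smoking"] = np.array(SMOKING_LEVELS)[(u[:, None] > cum).sum(axis=1)]
    df["alcohol"] = crng.choice(
        ["none", "rarely", "monthly", "weekly", "daily"], size=n,
        p=[0.70, 0.20, 0.04, 0.04, 0.02],
    )
    df["exercise"] = crng.choice(
        ["none", "le20min", "21_60min", "61_150min", "ge151min"], size=n,
        p=[0.25, 0.15, 0.25, 0.17, 0.18],
    )
    bmi = np.clip(crng.normal(27.5, 5.5, n), 15, 55)
    df["bmi"] = bmi
    df["bmi_category"] = pd.cut(
        bmi, [0, 18.5, 25, 30, np.inf],
        labels=["underweight", "normal", "overweight", "obese"], right=False,
    ).astype(str)
    age_c = (df["entry_age"] - 56.0) / 14.0
    df["diabetes"] = (crng.random(n) < 1 / (1 + np.exp(-(-2.4 + 0.5 * age_c)))).astype(int)
    df["hypertension"] = (crng.random(n) < 1 / (1 + np.exp(-(-1.3 + 0.7 * age_c)))).astype(int)
    df["multivitamin"] = (crng.random(n) < 0.47).astype(int)
    df["aspirin"] = (crng.random(n) < 0.16).astype(int)
    df["cancer_screening"] = (crng.random(n) < 0.55).astype(int)
    post = (df["sex"] == "F") & (df["entry_age"] + crng.normal(0, 3, n) > 51)
    df["postmenopausal"] = np.where(df["sex"] == "F", post.astype(float), np.nan)
    df["energy"] = np.exp(crng.normal(np.log(1900) - 0.38**2 / 2, 0.38, n))
    return df


# ---------------------------------------------------------------------------
# FFQ and recalls
# ---------------------------------------------------------------------------


def _perturb_log1p(x: np.ndarray, sd: float, rng) -> np.ndarray:
    """Classical error on the log1p scale; true zeros stay zero.

    Perturbed values are floored at 0 g/day (a reported intake cannot be
    negative), which slightly truncates the error's left tail for
    low-intake consumers.
    """
    out = np.zeros_like(x)
    pos = x > 0
    if sd == 0:
        out[pos] = x[pos]
    else:
        out[pos] = np.clip(
            np.expm1(np.log1p(x[pos]) + rng.normal(0.0, sd, pos.sum())), 0.0, None
        )
    return out


def generate_ffq_and_recalls(
    true_exposures: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FFQ g/day for the whole cohort; recall replicates for the substudy.

    The substudy is sampled with equal allocation across the two race
    groups, the usual design when validity is to be reported per group.
    """
    config.validate()
    rngs = config.streams()
    n = len(true_exposures)
    ffq = pd.DataFrame({"subject_id": true_exposures["subject_id"]})
    frng = rngs["ffq"]
    foods = [f for f in FOODS if f in config.exposure_distribution]
    for food in foods:
        ffq[f"ffq_{food}"] = _perturb_log1p(
            true_exposures[f"true_{food}"].to_numpy(), config.ffq_sd(food), frng
        )
    ffq["ffq_combined_red_processed"] = ffq["ffq_unprocessed_red"] + ffq["ffq_processed"]

    srng = rngs["substudy"]
    k = config.substudy_size
    idx_parts = []
    race = true_exposures["race"].to_numpy()
    for gval, share in (("Black", 0.5), ("non-Black", 0.5)):
        pool = np.flatnonzero(race == gval)
        take = min(int(round(k * share)), len(pool))
        idx_parts.append(srng.choice(pool, size=take, replace=False))
    sub_idx = np.sort(np.concatenate(idx_parts))
    rrng = rngs["recalls"]
    sub = true_exposures.iloc[sub_idx].reset_index(drop=True)
    out = {"subject_id": sub["subject_id"].to_numpy()}
    for food in foods:
        x = sub[f"true_{food}"].to_numpy()
        out[f"ffq_{food}"] = ffq[f"ffq_{food}"].to_numpy()[sub_idx]
        for j in range(config.n_recalls):
            out[f"recall_{food}_{j + 1}"] = _perturb_log1p(x, config.recall_sd(food), rrng)
    substudy = pd.DataFrame(out)
    for j in range(config.n_recalls):
        substudy[f"recall_combined_red_processed_{j + 1}"] = (
            substudy[f"recall_unprocessed_red_{j + 1}"] + substudy[f"recall_processed_{j + 1}"]
        )
    substudy["ffq_combined_red_processed"] = (
        substudy["ffq_unprocessed_red"] + substudy["ffq_processed"]
    )
    # carry covariates for calibration models
    covs = [c for c in sub.columns if not c.startswith("true_") and c != "subject_id"]
    for c in covs:
        substudy[c] = sub[c].to_numpy()
    return ffq, substudy


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


def _linear_predictor(true_exposures: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    eta = np.zeros(len(true_exposures))
    for key, b in config.true_log_hr.items():
        if key in config.exposure_distribution or key == "combined_red_processed":
            if key == "combined_red_processed":
                x = (
                    true_exposures["true_unprocessed_red"]
                    + true_exposures["true_processed"]
                ).to_numpy()
            else:
                x = true_exposures[f"true_{key}"].to_numpy()
            eta += b * np.log1p(x)
        elif "=" in key:
            col, level = key.split("=", 1)
            eta += b * (true_exposures[col].astype(str) == level).to_numpy(dtype=float)
        else:
            eta += b * true_exposures[key].to_numpy(dtype=float)
    if config.smoking_log_hr:
        eta += config.smoking_log_hr * (true_exposures["smoking"] != "never").to_numpy(float)
    return eta


def _piecewise_cumhaz(config):
    """Knot ages, per-interval rates, and cumulative hazard at the knots."""
    knots = np.asarray(config.piecewise_knots, dtype=float)
    if config.piecewise_rates is not None:
        rates = np.asarray(config.piecewise_rates, dtype=float)
        if len(rates) != len(knots) - 1:
            raise ValueError("need one piecewise rate per knot interval")
    else:
        mids = (knots[:-1] + knots[1:]) / 2.0
        k, lam = config.weibull_shape, config.weibull_scale
        rates = (k / lam) * (mids / lam) ** (k - 1.0)
    H_knots = np.concatenate([[0.0], np.cumsum(rates * np.diff(knots))])
    return knots, rates, H_knots


def generate_survival(true_exposures: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Left-truncated survival with cause-specific death codes.

    Death age is drawn by inverse-transform sampling conditional on survival
    to the entry age: with baseline cumulative hazard H0 and hazard
    multiplier theta, T = H0^{-1}(H0(a) - log U / theta). The Weibull
    baseline (H0(t) = (t/scale)^shape) has the closed form used as a test
    oracle; a piecewise-exponential baseline on an age grid is selectable
    with ``baseline="piecewise_exponential"``.
    """
    config.validate()
    rng = config.streams()["survival"]
    n = len(true_exposures)
    entry = true_exposures["entry_age"].to_numpy()
    theta = np.exp(_linear_predictor(true_exposures, config))
    u = rng.random(n)
    if config.baseline == "weibull":
        H0a = (entry / config.weibull_scale) ** config.weibull_shape
        T = config.weibull_scale * (H0a - np.log(u) / theta) ** (
            1.0 / config.weibull_shape
        )
    else:
        knots, rates, H_knots = _piecewise_cumhaz(config)
        seg = np.clip(np.searchsorted(knots, entry, side="right") - 1, 0, len(rates) - 1)
        H0a = H_knots[seg] + rates[seg] * (entry - knots[seg])
        target = H0a - np.log(u) / theta
        seg_t = np.clip(np.searchsorted(H_knots, target, side="right") - 1, 0, len(rates) - 1)
        T = knots[seg_t] + (target - H_knots[seg_t]) / rates[seg_t]
    fu = config.followup_years + rng.uniform(-config.followup_spread, config.followup_spread, n)
    censor_age = np.minimum(entry + fu, config.admin_censor_age)
    event = T <= censor_age
    exit_age = np.where(event, T, censor_age)
    exit_age = np.maximum(exit_age, entry + 1e-6)
    if event.sum() == 0 and n >= 10000:
        warnings.warn("baseline hazard produced zero events at n >= 10000")
    classes = list(config.cause_mixture)
    probs = np.array([config.cause_mixture[c] for c in classes])
    cls_idx = rng.choice(len(classes), size=n, p=probs)
    codes = np.array(
        [rng.choice(CAUSE_CODES[classes[i]]) for i in cls_idx], dtype=object
    )
    out = pd.DataFrame(
        {
            "subject_id": true_exposures["subject_id"],
            "entry_age": entry,
            "exit_age": exit_age,
            "death": event.astype(int),
            "cause_code": np.where(event, codes, ""),
        }
    )
    return out


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

PROTECTED_COLS = {"subject_id", "entry_age", "exit_age", "death", "cause_code"}


def inject_missingness(
    cohort: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set covariate cells to missing under a MAR mechanism.

    P(missing) depends only on fully observed sex and entry age, rescaled so
    the marginal rate equals the configured target. Returns the masked table
    and the boolean missingness mask.
    """
    config.validate()
    rng = config.streams()["missingness"]
    out = cohort.copy()
    mask = pd.DataFrame(False, index=cohort.index, columns=list(config.missing_rates))
    if not config.missing_rates:
        return out, mask
    age_c = (cohort["entry_age"].to_numpy(float) - 56.0) / 14.0
    female = (cohort["sex"] == "F").to_numpy(float)
    w = np.exp(0.4 * age_c - 0.3 * female)  # MAR driver: observed covariates only
    w = w / w.mean()
    for col, rate in config.missing_rates.items():
        if col in PROTECTED_COLS or col.startswith(("ffq_", "true_")):
            raise ValueError(f"missingness may only target covariates, not {col!r}")
        p = np.clip(rate * w, 0.0, 0.999)
        hit = rng.random(len(cohort)) < p
        mask[col] = hit
        out.loc[hit, col] = np.nan
    return out, mask


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------


def generate_dataset(config: SimulationConfig):
    """Full synthetic study: cohort, calibration substudy and ground truth.

    Ground truth (true intakes, latent correlation, configured hazards) is
    returned separately and is never an input to the analysis modules.
    """
    true = generate_true_exposures(config)
    ffq, substudy = generate_ffq_and_recalls(true, config)
    surv = generate_survival(true, config)
    covs = [c for c in true.columns if not c.startswith("true_") and c != "subject_id"]
    cohort = pd.concat(
        [
            true[["subject_id"]],
            ffq.drop(columns="subject_id"),
            true[covs],
            surv.drop(columns=["subject_id", "entry_age"]),
        ],
        axis=1,
    )
    cohort, mask = inject_missingness(cohort, config)
    truth = {
        "true_log_hr": dict(config.true_log_hr),
        "exposure_correlation_target": config.exposure_correlation,
        # validity = corr(FFQ, truth) on the log1p error scale, among consumers
        "true_validity": {
            f: float(
                log1p_scale_sd(d) / np.hypot(log1p_scale_sd(d), config.ffq_sd(f))
            )
            for f, d in config.exposure_distribution.items()
        },
        "seed": config.seed,
    }
    truth_table = true[["subject_id"] + [c for c in true.columns if c.startswith("true_")]]
    return cohort, substudy, truth, truth_table


def write_dataset(config: SimulationConfig, out_dir: str | Path):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, substudy, truth, truth_table = generate_dataset(config)
    fmt = dict(index=False, float_format="%.10g")
    cohort.to_csv(out / "cohort.csv", **fmt)
    substudy.to_csv(out / "substudy.csv", **fmt)
    truth_table.to_csv(out / "truth_table.csv", **fmt)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return cohort, substudy
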