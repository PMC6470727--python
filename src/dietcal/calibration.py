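"""Regression calibration of dietary measurement error.

A food-frequency questionnaire (FFQ) measures usual intake with error;
hazard ratios estimated from it are attenuated toward the null. In a
calibration substudy with replicate 24-h recalls, the mean recall intake is
regressed on the FFQ intake (plus the analytic covariates); predicted
recall intakes then replace the FFQ exposure in the outcome model, giving
calibrated hazard ratios. Confidence intervals for the calibrated
estimates come from a bias-corrected and accelerated (BCa) bootstrap that
resamples cohort and substudy subjects independently and (by default)
refits the calibration model in every replicate.

Calibration operates on the scale the Cox model uses (default log1p), i.e.
the error-prone variable actually entering the hazard model is the one
being calibrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cox import ContrastResult, HazardModel, fit_cox, get_transform

__all__ = [
    "CalibrationModel",
    "BootstrapResult",
    "fit_calibration",
    "predict_calibrated",
    "calibrated_hazard_ratio",
    "bootstrap_bca",
    "bca_endpoints",
    "deattenuate_correlation",
]


@dataclass
class CalibrationModel:
    """Linear model mapping FFQ intake to expected recall intake."""

    exposure: str
    intercept: float
    slope: float
    covariate_coefs: dict
    residual_variance: float
    n: int
    transform: str = "log1p"

    def predict(self, data: pd.DataFrame, ffq_col: str | None = None) -> pd.Series:
        g = get_transform(self.transform)
        x = g(data[ffq_col or self.exposure].to_numpy(float))
        yhat = self.intercept + self.slope * x
        for cov, b in self.covariate_coefs.items():
            v = data[cov]
            if v.isna().any():
                raise ValueError(f"covariate {cov!r} has missing values; impute first")
            yhat = yhat + b * v.to_numpy(float)
        return pd.Series(yhat, index=data.index)


def _ols(X: np.ndarray, y: np.ndarray, names: list[str]):
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-10 if diag.size else 0.0
    if np.any(diag < tol) or np.linalg.matrix_rank(X) < X.shape[1]:
        bad = [names[i] for i in np.where(diag < tol)[0]]
        raise ValueError(f"rank-deficient calibration design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    return beta, float(resid @ resid / dof)


def fit_calibration(
    substudy: pd.DataFrame,
    exposure: str,
    covariates: list[str] | None = None,
    recall_cols: list[str] | None = None,
    transform: str = "log1p",
    recall_summary: str = "mean",
) -> CalibrationModel:
    """OLS of the recall-summary intake on the FFQ intake plus covariates.

    ``exposure`` names the food group; the substudy must carry
    ``ffq_<exposure>`` and ``recall_<exposure>_<j>`` columns (or pass
    ``recall_cols``). Both sides are put on the model transform scale.
    """
    covariates = covariates or []
    ffq_col = f"ffq_{exposure}" if f"ffq_{exposure}" in substudy.columns else exposure
    if recall_cols is None:
        recall_cols = [c for c in substudy.columns if c.startswith(f"recall_{exposure}_")]
    if not recall_cols:
        raise ValueError(f"no recall replicate columns found for {exposure!r}")
    g = get_transform(transform)
    recalls = g(substudy[recall_cols].to_numpy(float))
    y = np.mean(recalls, axis=1) if recall_summary == "mean" else np.median(recalls, axis=1)
    x = g(substudy[ffq_col].to_numpy(float))
    Z = substudy[covariates].to_numpy(float) if covariates else np.empty((len(substudy), 0))
    X = np.column_stack([np.ones(len(substudy)), x, Z])
    names = ["intercept", ffq_col] + list(covariates)
    beta, s2 = _ols(X, y, names)
    return CalibrationModel(
        exposure=ffq_col,
        intercept=float(beta[0]),
        slope=float(beta[1]),
        covariate_coefs=dict(zip(covariates, beta[2:].tolist())),
        residual_variance=s2,
        n=len(substudy),
        transform=transform,
    )


def predict_calibrated(
    cohort: pd.DataFrame, model: CalibrationModel, ffq_col: str | None = None
) -> pd.Series:
    """Calibrated exposure column (predicted recall intake, model scale)."""
    return model.predict(cohort, ffq_col=ffq_col)


def calibrated_hazard_ratio(
    cohort: pd.DataFrame,
    substudy: pd.DataFrame,
    exposure: str,
    covariates: list[str] | None = None,
    calibration_covariates: list[str] | None = None,
    x1: float | None = None,
    x0: float = 0.0,
    percentile: float = 0.9,
    transform: str = "log1p",
    ties: str = "efron",
    alpha: float = 0.05,
) -> tuple[ContrastResult, HazardModel, CalibrationModel]:
    """Two-stage calibrated HR for the x1-vs-x0 exposure contrast.

    Stages: fit the calibration model on the substudy, predict calibrated
    exposures for the cohort, fit the Cox model with the calibrated column
    plus ``covariates`` (which must exclude the exposure itself and exist
    in both tables), then form the contrast. By default the calibration
    model controls for the same covariates as the analytic model.

    The calibrated column lives on the reference-instrument (recall) intake
    scale, so the 90th-percentile-vs-zero contrast is applied directly to
    its coefficient: HR = exp(beta_cal * (g(x1) - g(x0))). Because
    beta_cal ~ beta_naive / slope, this undoes the attenuation (a slope
    below 1 widens the contrast), mirroring the calibrated > uncalibrated
    pattern expected under classical error.
    """
    covariates = list(covariates or [])
    calibration_covariates = (
        list(covariates) if calibration_covariates is None else list(calibration_covariates)
    )
    ffq_col = f"ffq_{exposure}" if f"ffq_{exposure}" in cohort.columns else exposure
    try:
        cal = fit_calibration(substudy, exposure, calibration_covariates, transform=transform)
    except Exception as e:
        raise RuntimeError(f"calibration stage failed: {e}") from e
    df = cohort.copy()
    cal_col = f"calibrated_{exposure}"
    try:
        df[cal_col] = predict_calibrated(df, cal, ffq_col=ffq_col)
    except Exception as e:
        raise RuntimeError(f"prediction stage failed: {e}") from e
    cox_terms = [cal_col] + covariates
    try:
        model = fit_cox(df, cox_terms, ties=ties)
    except Exception as e:
        raise RuntimeError(f"hazard-model stage failed: {e}") from e
    if x1 is None:
        x1 = float(np.quantile(cohort[ffq_col], percentile))
    from .cox import contrast_hr

    contrast = contrast_hr(model, cal_col, x1, x0, transform=transform, alpha=alpha)
    return contrast, model, cal


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """BCa interval with its bias-correction and acceleration constants."""

    estimate: float
    replicates: np.ndarray
    z0: float
    a: float
    ci_low: float
    ci_high: float
    alpha: float
    n_failed: int = 0
    degenerate: bool = False


def _jackknife_units(n: int, max_exact: int, n_blocks: int) -> list[np.ndarray]:
    """Leave-one-out deletions, or contiguous delete-blocks for large n.

    The acceleration ratio is invariant to the block size for iid rows
    (both the third-moment numerator and the variance denominator aggregate
    block sums identically), so delete-blocks estimate the same constant.
    """
    if n <= max_exact:
        return [np.delete(np.arange(n), i) for i in range(n)]
    bounds = np.linspace(0, n, min(n_blocks, n) + 1).astype(int)
    idx = np.arange(n)
    return [np.concatenate([idx[: a], idx[b:]]) for a, b in zip(bounds[:-1], bounds[1:])]


def bootstrap_bca(
    statistic,
    data_tables: dict,
    B: int = 4000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    jackknife_max_exact: int = 2000,
    jackknife_blocks: int = 200,
    max_failure_rate: float = 0.05,
) -> BootstrapResult:
    """Bias-corrected and accelerated bootstrap CI for a table statistic.

    ``statistic`` is a pure function of the tables (called as
    ``statistic(**data_tables)``); every table's rows are resampled with
    replacement independently. z0 is the normal quantile of the fraction of
    replicates below the point estimate; the acceleration constant comes
    from the jackknife skewness of leave-one-unit-out estimates (contiguous
    delete-blocks once a table exceeds ``jackknife_max_exact`` units, for
    tractability). Deterministic given the seed.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tables = {k: v.reset_index(drop=True) for k, v in data_tables.items()}
    theta = float(statistic(**tables))
    reps = []
    failed = 0
    for _ in range(B):
        boot = {
            k: v.take(rng.integers(0, len(v), len(v))).reset_index(drop=True)
            for k, v in tables.items()
        }
        try:
            reps.append(float(statistic(**boot)))
        except Exception:
            failed += 1
    if failed > max_failure_rate * B:
        raise RuntimeError(f"{failed}/{B} bootstrap replicates failed to refit")
    reps = np.asarray(reps)
    if np.allclose(reps, reps[0]):
        warnings.warn("all bootstrap replicates identical; degenerate point-mass CI")
        return BootstrapResult(theta, reps, 0.0, 0.0, reps[0], reps[0], alpha, failed, True)
    # bias correction
    frac = np.mean(reps < theta)
    frac = np.clip(frac, 1.0 / (len(reps) + 1), len(reps) / (len(reps) + 1.0))
    z0 = float(stats.norm.ppf(frac))
    # acceleration from jackknife over all tables' units
    jack = []
    for key in tables:
        keep_others = {k: v for k, v in tables.items() if k != key}
        for keep in _jackknife_units(len(tables[key]), jackknife_max_exact, jackknife_blocks):
            sub = dict(keep_others)
            sub[key] = tables[key].iloc[keep].reset_index(drop=True)
            try:
                jack.append(float(statistic(**sub)))
            except Exception:
                pass
    jack = np.asarray(jack)
    if len(jack) < 3 or np.allclose(jack, jack.mean()):
        a = 0.0
    else:
        dev = jack.mean() - jack
        denom = 6.0 * (dev @ dev) ** 1.5
        a = float((dev**3).sum() / denom) if denom > 0 else 0.0
    lo, hi = bca_endpoints(reps, z0, a, alpha)
    return BootstrapResult(theta, reps, z0, a, lo, hi, alpha, failed)


def bca_endpoints(replicates: np.ndarray, z0: float, a: float, alpha: float = 0.05):
    """Replicate quantiles at the BCa-adjusted levels.

    With z0 = 0 and a = 0 the adjusted levels are exactly alpha/2 and
    1 - alpha/2, so the interval equals the percentile interval.
    """
    if z0 == 0.0 and a == 0.0:  # exact percentile interval, no float fuzz
        levels = [alpha / 2, 1 - alpha / 2]
    else:
        zlo, zhi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
        adj = lambda z: stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        levels = [adj(zlo), adj(zhi)]
    lo, hi = np.quantile(np.asarray(replicates), levels, method="linear")
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Validity / deattenuation
# ---------------------------------------------------------------------------


def deattenuate_correlation(
    ffq, recall_replicates, log_scale: bool = True, consumers_only: bool = True
) -> dict:
    """Deattenuated FFQ validity correlation from replicate recalls.

    The observed correlation of the FFQ with the k-replicate recall mean is
    inflated for within-person recall variation:
    r_true = r_obs * sqrt(1 + lambda/k), with lambda the within- to
    between-person variance ratio from one-way ANOVA components of the
    recalls. Values pushed past |1| are clipped with a warning.
    """
    f = np.asarray(ffq, dtype=float)
    R = np.asarray(recall_replicates, dtype=float)
    if R.ndim != 2 or R.shape[1] < 2:
        raise ValueError("need >= 2 recall replicates per subject")
    if consumers_only:
        keep = (f > 0) & (R > 0).all(axis=1)
        f, R = f[keep], R[keep]
    if log_scale:
        f, R = np.log1p(f), np.log1p(R)
    n, k = R.shape
    means = R.mean(axis=1)
    msw = float(((R - means[:, None]) ** 2).sum() / (n * (k - 1)))
    msb = float(k * ((means - means.mean()) ** 2).sum() / (n - 1))
    var_between = (msb - msw) / k
    if var_between <= 0:
        raise ValueError("non-positive between-person recall variance; no usable signal")
    lam = msw / var_between
    r_obs = float(np.corrcoef(f, means)[0, 1])
    r_true = r_obs * np.sqrt(1.0 + lam / k)
    if abs(r_true) > 1.0:
        warnings.warn(f"deattenuated correlation {r_true:.3f} clipped to [-1, 1]")
        r_true = float(np.clip(r_true, -1.0, 1.0))
    return {
        "r_observed": r_obs,
        "r_deattenuated": float(r_true),
        "lambda": float(lam),
        "k": int(k),
        "n": int(n),
    }
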