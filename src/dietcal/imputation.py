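"""Multiple imputation of covariates and Rubin's-rules pooling.

Chained-equations imputation: each incomplete covariate is modelled on the
other covariates; continuous targets use predictive-mean matching (PMM,
5 donors) with parameter uncertainty injected by fitting each imputation's
models on a bootstrap resample of the complete cases; categorical targets
use multinomial-logistic draws. Exposure and outcome columns are never
imputed. Estimates fitted on the m completed tables are pooled with
Rubin's rules: pooled beta = mean, total variance T = W + (1 + 1/m) * B,
small-sample t reference with the Barnard-Rubin style degrees of freedom
nu = (m - 1) * (1 + W / ((1 + 1/m) B))^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ImputedSet", "PooledEstimate", "impute", "rubin_pool"]


@dataclass
class ImputedSet:
    datasets: list
    method: dict
    seed: int
    m: int


@dataclass
class PooledEstimate:
    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    ci_low: float
    ci_high: float
    p_value: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def _design_for(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    """Numeric design matrix: dummies for object/category predictors."""
    parts = [np.ones((len(df), 1))]
    for c in predictors:
        v = df[c]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(v.astype(str), drop_first=True, dtype=float)
            parts.append(d.to_numpy())
        else:
            parts.append(v.to_numpy(float)[:, None])
    return np.hstack(parts)


def _pmm_impute(y_obs, X_obs, X_mis, rng, n_donors=5):
    boot = rng.integers(0, len(y_obs), len(y_obs))
    beta, *_ = np.linalg.lstsq(X_obs[boot], y_obs[boot], rcond=None)
    pred_obs = X_obs @ beta
    pred_mis = X_mis @ beta
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    out = np.empty(len(pred_mis))
    for i, p in enumerate(pred_mis):
        j = np.searchsorted(sorted_pred, p)
        lo = max(0, j - n_donors)
        hi = min(len(sorted_pred), j + n_donors)
        cand = order[lo:hi]
        d = np.abs(pred_obs[cand] - p)
        donors = cand[np.argsort(d, kind="stable")[:n_donors]]
        out[i] = y_obs[donors[rng.integers(0, len(donors))]]
    return out


def _multinomial_impute(y_obs, X_obs, X_mis, rng):
    from sklearn.linear_model import LogisticRegression

    levels, codes = np.unique(y_obs, return_inverse=True)
    if len(levels) == 1:
        return np.repeat(levels[0], len(X_mis))
    # standardize (sans intercept column) so lbfgs converges
    mu, sd = X_obs.mean(axis=0), X_obs.std(axis=0)
    sd[sd == 0] = 1.0
    Xo, Xm = (X_obs - mu) / sd, (X_mis - mu) / sd
    boot = rng.integers(0, len(codes), len(codes))
    if len(np.unique(codes[boot])) < len(levels):  # keep every class present
        boot = np.concatenate([boot, [np.flatnonzero(codes == k)[0] for k in range(len(levels))]])
    clf = LogisticRegression(max_iter=500, C=10.0)
    clf.fit(Xo[boot], codes[boot])
    probs = clf.predict_proba(Xm)
    u = rng.random(len(X_mis))
    draw = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    draw = np.clip(draw, 0, len(clf.classes_) - 1)
    return levels[clf.classes_[draw]]


def impute(
    cohort: pd.DataFrame,
    m: int = 5,
    seed: int = 0,
    columns: list[str] | None = None,
    predictors: list[str] | None = None,
    exclude: tuple = (
        "subject_id",
        "entry_age",
        "exit_age",
        "death",
        "cause_code",
        "postmenopausal",  # structurally missing for men, not MAR
    ),
    n_iter: int = 5,
) -> ImputedSet:
    """Chained-equations multiple imputation of incomplete covariates.

    ``columns`` defaults to every column with missing cells (except
    ``exclude`` and ffq/true exposure columns); ``predictors`` defaults to
    all other covariates plus entry age. Deterministic given ``seed``.
    """
    targets = columns or [
        c
        for c in cohort.columns
        if cohort[c].isna().any()
        and c not in exclude
        and not c.startswith(("ffq_", "true_", "recall_"))
    ]
    bad = [c for c in targets if c in exclude or c.startswith(("ffq_", "true_"))]
    if bad:
        raise ValueError(f"refusing to impute exposure/outcome columns: {bad}")
    for c in targets:
        frac = cohort[c].isna().mean()
        if frac == 1.0:
            raise ValueError(f"column {c!r} entirely missing; cannot impute")
        if frac > 0.5:
            warnings.warn(f"column {c!r} is {frac:.0%} missing")
    if not targets:
        return ImputedSet([cohort.copy() for _ in range(m)], {}, seed, m)
    if predictors is None:
        predictors = [
            c
            for c in cohort.columns
            if c not in targets
            and c not in ("subject_id", "cause_code", "exit_age", "death")
            and not c.startswith(("true_", "recall_"))
            and not cohort[c].isna().any()  # non-target predictors must be complete
        ]
    methods = {}
    rng_master = np.random.SeedSequence(seed).spawn(m)
    datasets = []
    for imp_idx in range(m):
        rng = np.random.default_rng(rng_master[imp_idx])
        df = cohort.copy()
        # initial fill: random observed draws
        for c in targets:
            miss = df[c].isna()
            obs = df.loc[~miss, c].to_numpy()
            df.loc[miss, c] = obs[rng.integers(0, len(obs), miss.sum())]
        for _ in range(n_iter):
            for c in targets:
                miss = cohort[c].isna().to_numpy()
                preds = [p for p in predictors if p != c]
                X = _design_for(df, preds)
                y_all = cohort[c]
                numeric = pd.api.types.is_numeric_dtype(y_all.dropna())
                if numeric:
                    methods[c] = "pmm"
                    imp = _pmm_impute(
                        y_all[~miss].to_numpy(float), X[~miss], X[miss], rng
                    )
                else:
                    methods[c] = "multinomial_logit"
                    imp = _multinomial_impute(
                        y_all[~miss].to_numpy(object), X[~miss], X[miss], rng
                    )
                df.loc[miss, c] = imp
        for c in targets:  # restore dtypes disturbed by the NaN passage
            if pd.api.types.is_numeric_dtype(cohort[c].dropna()):
                df[c] = df[c].astype(float)
        datasets.append(df)
    return ImputedSet(datasets, methods, seed, m)


def rubin_pool(
    estimates, variances, alpha: float = 0.05
) -> PooledEstimate:
    """Pool one scalar estimate across m imputations with Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.ndim != 1 or q.shape != u.shape or len(q) < 2:
        raise ValueError("need m >= 2 matching estimates and variances")
    m = len(q)
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if B > 0:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
    else:
        df = np.inf
    se = np.sqrt(T)
    tcrit = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else stats.norm.ppf(1 - alpha / 2)
    if se > 0:
        p = float(2 * (stats.t.sf(abs(qbar) / se, df) if np.isfinite(df) else stats.norm.sf(abs(qbar) / se)))
    else:
        p = float(qbar == 0.0)
    return PooledEstimate(
        estimate=qbar,
        within_variance=W,
        between_variance=B,
        total_variance=float(T),
        df=float(df),
        ci_low=float(qbar - tcrit * se),
        ci_high=float(qbar + tcrit * se),
        p_value=p,
        m=m,
    )
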