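"""Cox proportional-hazards estimation on the attained-age time scale.

Subjects enter the risk set at their study-entry age (left truncation) and
leave at their exit age; analysis time is attained age. The partial
likelihood is maximized by Newton-Raphson with either Efron's (default) or
Breslow's treatment of tied event ages. The module also provides the
downstream procedures an epidemiological mortality analysis needs: cause
classification from ICD-10 codes, hazard-ratio contrasts on a transformed
exposure scale, quartile-median trend tests, restricted cubic spline
nonlinearity tests, proportional-hazards diagnostics (scaled Schoenfeld
residuals and attained-age interactions), and effect-modification tests.

The risk set at event age t is {i : entry_i < t <= exit_i}. Risk-set sums
are evaluated with two suffix-cumulative accumulators (one ordered by exit
age, one by entry age) so a full likelihood/gradient/information pass is
O(n log n + m p^2) for m distinct event ages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HazardModel",
    "ContrastResult",
    "ConvergenceError",
    "classify_cause",
    "event_indicator",
    "fit_cox",
    "contrast_hr",
    "trend_test",
    "rcs_knots",
    "rcs_basis",
    "nonlinearity_test",
    "ph_diagnostics",
    "interaction_test",
    "loglog_plot_data",
]

EXPOSURE_TRANSFORMS = {
    "log1p": np.log1p,
    "identity": lambda x: np.asarray(x, dtype=float),
}


def get_transform(name: str):
    """Resolve an exposure-transform name; 'log_offset(c)' is accepted."""
    if name in EXPOSURE_TRANSFORMS:
        return EXPOSURE_TRANSFORMS[name]
    m = re.fullmatch(r"log_offset\(([0-9.eE+-]+)\)", name)
    if m:
        c = float(m.group(1))
        if c <= 0:
            raise ValueError("log_offset constant must be > 0")
        return lambda x, _c=c: np.log(np.asarray(x, dtype=float) + _c)
    raise ValueError(f"unknown exposure transform {name!r}")


class ConvergenceError(RuntimeError):
    """Raised when Newton-Raphson fails, carrying the last gradient norm."""

    def __init__(self, message: str, grad_norm: float | None = None):
        super().__init__(message)
        self.grad_norm = grad_norm


# ---------------------------------------------------------------------------
# Cause-of-death classification
# ---------------------------------------------------------------------------

_ICD_RE = re.compile(r"^([A-Z])(\d{2})(?:\.\d+)?$")

UNNATURAL_LETTERS = frozenset("UVWXY")


def classify_cause(icd10_code: str) -> str:
    """Map an ICD-10 underlying-cause code to an analysis outcome class.

    Returns one of ``cvd`` (I00-I78), ``cancer`` (C00-C97),
    ``unnatural_censor`` (letters U, V, W, X, Y: censored at death, never an
    all-cause case) or ``other_natural``.
    """
    m = _ICD_RE.match(str(icd10_code).strip())
    if m is None:
        raise ValueError(f"malformed ICD-10 code: {icd10_code!r}")
    letter, num = m.group(1), int(m.group(2))
    if letter in UNNATURAL_LETTERS:
        return "unnatural_censor"
    if letter == "I" and 0 <= num <= 78:
        return "cvd"
    if letter == "C" and 0 <= num <= 97:
        return "cancer"
    return "other_natural"


def event_indicator(death: np.ndarray, cause_code: pd.Series, outcome: str) -> np.ndarray:
    """Event indicator for a cause-specific (or all-cause) analysis.

    Deaths from other natural causes are censoring events for ``cvd`` and
    ``cancer``; unnatural deaths are censored for every outcome, including
    all-cause.
    """
    death = np.asarray(death, dtype=bool)
    classes = np.array(
        [classify_cause(c) if d else "" for d, c in zip(death, cause_code)], dtype=object
    )
    if outcome == "all_cause":
        return death & (classes != "unnatural_censor")
    if outcome in ("cvd", "cancer"):
        return death & (classes == outcome)
    raise ValueError(f"unknown outcome {outcome!r}")


# ---------------------------------------------------------------------------
# Partial likelihood machinery
# ---------------------------------------------------------------------------


@dataclass
class HazardModel:
    """Fitted Cox model: coefficients, covariance, and fit metadata."""

    terms: list[str]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    ties: str
    n_iter: int
    converged: bool
    loglik_null: float = np.nan
    event_ages: np.ndarray | None = field(default=None, repr=False)
    schoenfeld: np.ndarray | None = field(default=None, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def wald_p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        se = self.se
        z = stats.norm.ppf(0.975)
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": se,
                "hr": np.exp(self.beta),
                "hr_low": np.exp(self.beta - z * se),
                "hr_high": np.exp(self.beta + z * se),
                "p": self.wald_p(),
            },
            index=self.terms,
        )


class _CoxData:
    """Pre-sorted arrays reused across Newton-Raphson iterations."""

    def __init__(self, entry, exit_, event, X, ties):
        entry = np.asarray(entry, dtype=float)
        exit_ = np.asarray(exit_, dtype=float)
        event = np.asarray(event, dtype=bool)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if np.any(exit_ <= entry):
            raise ValueError("exit age must exceed entry age for every subject")
        if event.sum() == 0:
            raise ValueError("no events in the data")
        self.n, self.p = X.shape
        self.ties = ties
        self.ord_exit = np.argsort(exit_, kind="stable")
        self.exit_sorted = exit_[self.ord_exit]
        self.X_exit = X[self.ord_exit]
        self.ord_entry = np.argsort(entry, kind="stable")
        self.entry_sorted = entry[self.ord_entry]
        self.X_entry = X[self.ord_entry]
        # events grouped by (unique) event age
        ev_times = exit_[event]
        ev_X = X[event]
        o = np.argsort(ev_times, kind="stable")
        ev_times = ev_times[o]
        ev_X = ev_X[o]
        self.te, start = np.unique(ev_times, return_index=True)
        self.m = len(self.te)
        self.d = np.diff(np.append(start, len(ev_times))).astype(float)
        self.ev_X = ev_X
        self.ev_start = start
        # index of first subject with exit >= te (side='left')
        self.idx_exit = np.searchsorted(self.exit_sorted, self.te, side="left")
        # subjects with entry >= te must be removed from the risk set
        self.idx_entry = np.searchsorted(self.entry_sorted, self.te, side="left")
        self.X = X
        self.event = event
        self.entry = entry
        self.exit_ = exit_
        # Efron inner-sum layout
        self.dmax = int(self.d.max())
        lgrid = np.arange(self.dmax, dtype=float)[None, :]  # (1, dmax)
        self.lmask = lgrid < self.d[:, None]  # (m, dmax)
        if ties == "efron":
            self.lfrac = np.where(self.lmask, lgrid / self.d[:, None], 0.0)
        elif ties == "breslow":
            self.lfrac = np.zeros_like(self.lmask, dtype=float)
        else:
            raise ValueError(f"unknown ties method {ties!r}")

    def _suffix_at(self, values, idx):
        """Suffix sums of `values` (n,...) evaluated at sorted indices.

        One reduceat pass over the event-boundary segments plus a suffix
        cumsum across the (few) segments; avoids a full-length cumsum of
        the n x p x p outer-product array.
        """
        n = len(values)
        inside = idx < n
        starts = np.unique(np.concatenate([[0], idx[inside]]))
        seg = np.add.reduceat(values, starts, axis=0)
        suf = np.cumsum(seg[::-1], axis=0)[::-1]
        out = np.zeros((len(idx),) + values.shape[1:])
        pos = np.searchsorted(starts, idx[inside])
        out[inside] = suf[pos]
        return out

    def _suffix_outer_at(self, X, r, idx):
        """Suffix sums of r_i x_i x_i' at sorted indices, via per-segment
        BLAS products (X_seg' diag(r_seg) X_seg) and a segment cumsum."""
        n, p = X.shape
        inside = idx < n
        starts = np.unique(np.concatenate([[0], idx[inside]]))
        ends = np.append(starts[1:], n)
        seg = np.empty((len(starts), p, p))
        for j, (a, b) in enumerate(zip(starts, ends)):
            seg[j] = X[a:b].T @ (X[a:b] * r[a:b, None])
        suf = np.cumsum(seg[::-1], axis=0)[::-1]
        out = np.zeros((len(idx), p, p))
        out[inside] = suf[np.searchsorted(starts, idx[inside])]
        return out

    def risk_sums(self, r, want_info=True):
        """S0 (m,), S1 (m,p), S2 (m,p,p) over left-truncated risk sets."""
        r_ex = r[self.ord_exit]
        r_en = r[self.ord_entry]
        S0 = self._suffix_at(r_ex, self.idx_exit) - self._suffix_at(r_en, self.idx_entry)
        S1 = self._suffix_at(r_ex[:, None] * self.X_exit, self.idx_exit) - self._suffix_at(
            r_en[:, None] * self.X_entry, self.idx_entry
        )
        if not want_info:
            return S0, S1, None
        S2 = self._suffix_outer_at(self.X_exit, r_ex, self.idx_exit) - self._suffix_outer_at(
            self.X_entry, r_en, self.idx_entry
        )
        return S0, S1, S2

    def tie_sums(self, r, want_info=True):
        """Sums of r, r*x, r*xx' over the tied events at each event age."""
        ev_r = r[self.event]
        o = np.argsort(self.exit_[self.event], kind="stable")
        ev_r = ev_r[o]
        s0 = np.add.reduceat(ev_r, self.ev_start)
        s1 = np.add.reduceat(ev_r[:, None] * self.ev_X, self.ev_start, axis=0)
        if not want_info:
            return s0, s1, None
        O = ev_r[:, None, None] * self.ev_X[:, :, None] * self.ev_X[:, None, :]
        s2 = np.add.reduceat(O, self.ev_start, axis=0)
        return s0, s1, s2

    def loglik_grad_info(self, beta, want_info=True):
        eta0 = self.X @ beta
        shift = eta0.max()  # overflow guard; cancels in ratios, restored in ll
        eta = eta0 - shift
        r = np.exp(eta)
        S0, S1, S2 = self.risk_sums(r, want_info=want_info)
        s0d, s1d, s2d = self.tie_sums(r, want_info=want_info)
        f = self.lfrac  # (m, dmax)
        mask = self.lmask
        denom = S0[:, None] - f * s0d[:, None]  # (m, dmax)
        if np.any(denom[mask] <= 0):
            raise FloatingPointError("non-positive risk-set sum (numerical degeneracy)")
        # each of the mask.sum() log-denominator terms carries e^{shift}
        ll = float(eta0[self.event].sum() - np.log(denom[mask]).sum() - shift * mask.sum())
        # gradient
        num1 = S1[:, None, :] - f[:, :, None] * s1d[:, None, :]  # (m, dmax, p)
        ratio1 = np.where(mask[:, :, None], num1 / denom[:, :, None], 0.0)
        grad = self.X[self.event].sum(axis=0) - ratio1.sum(axis=(0, 1))
        if not want_info:
            return ll, grad, None
        # information
        num2 = S2[:, None, :, :] - f[:, :, None, None] * s2d[:, None, :, :]
        ratio2 = np.where(mask[:, :, None, None], num2 / denom[:, :, None, None], 0.0)
        # masked slots of ratio1 are exactly zero, so their outer products vanish
        info = ratio2.sum(axis=(0, 1)) - np.einsum("mlp,mlq->pq", ratio1, ratio1)
        return ll, grad, info

    def schoenfeld_residuals(self, beta):
        """Per-event Schoenfeld residuals (Efron-averaged under ties).

        Rows ordered by event age; residuals of tied events share the same
        averaged risk-set mean. Their column sums equal the score, hence ~0
        at the MLE.
        """
        eta = self.X @ beta
        eta = eta - eta.max()
        r = np.exp(eta)
        S0, S1, _ = self.risk_sums(r, want_info=False)
        s0d, s1d, _ = self.tie_sums(r, want_info=False)
        f, mask = self.lfrac, self.lmask
        denom = S0[:, None] - f * s0d[:, None]
        num1 = S1[:, None, :] - f[:, :, None] * s1d[:, None, :]
        ratio1 = np.where(mask[:, :, None], num1 / denom[:, :, None], 0.0)
        mean_x = ratio1.sum(axis=1) / self.d[:, None]  # (m, p): Efron average
        resid = self.ev_X - np.repeat(mean_x, self.d.astype(int), axis=0)
        times = np.repeat(self.te, self.d.astype(int))
        return times, resid


def _design(data: pd.DataFrame, terms: list[str]) -> np.ndarray:
    X = data[terms].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [t for t in terms if data[t].isna().any()]
        raise ValueError(f"missing values in model terms {bad}; impute first")
    return X


def _check_degenerate(X, terms):
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [t for t, s in zip(terms, sd) if s == 0]
        raise ValueError(f"constant model terms: {bad}")


def fit_cox(
    data: pd.DataFrame,
    terms: list[str],
    entry_col: str = "entry_age",
    exit_col: str = "exit_age",
    event_col: str = "event",
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-8,
    step_tol: float = 1e-9,
    keep_residuals: bool = False,
) -> HazardModel:
    """Fit a left-truncated Cox model by Newton-Raphson.

    Converges when the score's infinity norm drops below ``tol`` or the
    Newton step below ``step_tol`` (at large n the accumulated risk-set
    sums have a floating-point noise floor above ``tol``; the step
    criterion then bounds the coefficient error by ~step_tol). Raises
    :class:`ConvergenceError` on non-convergence or monotone likelihood
    (separation).
    """
    X = _design(data, terms)
    if np.any(data[exit_col].to_numpy(float) <= data[entry_col].to_numpy(float)):
        raise ValueError("exit age must exceed entry age for every subject")
    _check_degenerate(X, terms)
    sdx = X.std(axis=0)
    # center covariates for conditioning; beta is invariant to shifts
    cd_c = _CoxData(data[entry_col], data[exit_col], data[event_col], X - X.mean(axis=0), ties)
    beta = np.zeros(cd_c.p)
    ll0, _, _ = cd_c.loglik_grad_info(beta, want_info=False)
    ll_prev = ll0
    converged = False
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        ll, grad, info = cd_c.loglik_grad_info(beta)
        grad_norm = float(np.abs(grad).max())
        if grad_norm < tol:
            converged = True
            ll_prev = ll
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular information matrix: {e}", grad_norm)
        # step-halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            try:
                ll_new, _, _ = cd_c.loglik_grad_info(cand, want_info=False)
            except FloatingPointError:
                ll_new = -np.inf
            if ll_new >= ll - 1e-10 * (1 + abs(ll)):
                break
            scale *= 0.5
        beta = beta + scale * step
        ll_prev = ll_new
        if scale * float(np.abs(step).max()) < step_tol * (1.0 + float(np.abs(beta).max())):
            converged = True
            break
        if np.abs(beta * sdx).max() > 10:
            # a log-HR beyond 10 per covariate SD means the likelihood is
            # still climbing toward infinity (perfect separation)
            raise ConvergenceError(
                "monotone likelihood: coefficient diverging (possible perfect "
                f"separation); max |beta|*sd = {np.abs(beta * sdx).max():.1f}",
                grad_norm,
            )
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations; last gradient norm {grad_norm:.3e}",
            grad_norm,
        )
    if np.abs(beta * sdx).max() > 10:
        raise ConvergenceError(
            "monotone likelihood: score vanished at an extreme coefficient "
            f"(perfect separation); max |beta|*sd = {np.abs(beta * sdx).max():.1f}",
            grad_norm,
        )
    ll, grad, info = cd_c.loglik_grad_info(beta)
    cov = np.linalg.inv(info)
    cov = (cov + cov.T) / 2.0
    model = HazardModel(
        terms=list(terms),
        beta=beta,
        cov=cov,
        loglik=ll,
        n=cd_c.n,
        n_events=int(cd_c.d.sum()),
        ties=ties,
        n_iter=it,
        converged=converged,
        loglik_null=ll0,
    )
    if keep_residuals:
        times, resid = cd_c.schoenfeld_residuals(beta)
        model.event_ages = times
        model.schoenfeld = resid
    return model


# ---------------------------------------------------------------------------
# Contrasts, trend, splines, diagnostics, interactions
# ---------------------------------------------------------------------------


@dataclass
class ContrastResult:
    """Hazard ratio with CI and p-value for a defined exposure contrast."""

    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    description: str

    def __post_init__(self):
        if not (self.ci_low <= self.hr <= self.ci_high) and np.isfinite(self.hr):
            raise ValueError("contrast CI must enclose the point estimate")


def contrast_hr(
    model: HazardModel,
    term: str,
    x1: float,
    x0: float,
    transform: str = "log1p",
    alpha: float = 0.05,
    scale: float = 1.0,
) -> ContrastResult:
    """HR comparing exposure x1 vs x0 on the model's transformed scale.

    ``scale`` multiplies the transformed difference (used when the model
    term is a linear map of the transformed exposure, e.g. a calibrated
    predictor with known slope).
    """
    if term not in model.terms:
        raise ValueError(f"term {term!r} not in model")
    g = get_transform(transform)
    delta = float(scale * (g(np.array([x1]))[0] - g(np.array([x0]))[0]))
    if delta == 0.0:
        raise ValueError(f"degenerate contrast: g({x1}) == g({x0})")
    j = model.terms.index(term)
    est = model.beta[j] * delta
    se = float(np.sqrt(model.cov[j, j]) * abs(delta))
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
    return ContrastResult(
        hr=float(np.exp(est)),
        ci_low=float(np.exp(est - z * se)),
        ci_high=float(np.exp(est + z * se)),
        p_value=float(p),
        description=f"{term}: {x1} vs {x0} ({transform}, scale={scale:g})",
    )


def trend_test(
    data: pd.DataFrame,
    category_col: str,
    category_medians: dict,
    terms: list[str],
    **fit_kw,
) -> float:
    """Wald p for linear trend across intake categories.

    Every subject is assigned the median intake of their category and the
    median-valued score is analyzed as a continuous variable (zero-intake
    level scores its median, 0).
    """
    cats = data[category_col]
    unknown = set(cats.unique()) - set(category_medians)
    if unknown:
        raise ValueError(f"categories without medians: {sorted(unknown)}")
    score = cats.map(category_medians).astype(float)
    df = data.copy()
    df["_trend_score"] = score
    model = fit_cox(df, ["_trend_score"] + [t for t in terms if t != category_col], **fit_kw)
    return float(model.wald_p()[0])


def rcs_knots(x: np.ndarray, n_knots: int = 4) -> np.ndarray:
    """Default knot placement at the 5/35/65/95 percentiles (4 knots)."""
    if n_knots == 4:
        q = [5, 35, 65, 95]
    elif n_knots == 3:
        q = [10, 50, 90]
    elif n_knots == 5:
        q = [5, 27.5, 50, 72.5, 95]
    else:
        raise ValueError("n_knots must be 3, 4 or 5")
    return np.percentile(np.asarray(x, float), q)


def rcs_basis(x: np.ndarray, knots: np.ndarray | None = None, n_knots: int = 4) -> np.ndarray:
    """Restricted (natural) cubic spline basis, linear beyond boundary knots.

    Returns an (n, K-1) matrix whose first column is x itself; the remaining
    K-2 columns are the truncated-power nonlinear terms normalized by the
    squared knot span, so all columns are on roughly the scale of x.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if len(np.unique(x)) < 20:
            raise ValueError("need >= 20 distinct values to place spline knots")
        knots = rcs_knots(x, n_knots)
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("spline knots must be strictly increasing")
    K = len(knots)
    tk, tk1 = knots[-1], knots[-2]
    norm = (tk - knots[0]) ** 2
    cols = [x]
    pos3 = lambda u: np.clip(u, 0.0, None) ** 3
    for j in range(K - 2):
        tj = knots[j]
        c = (
            pos3(x - tj)
            - pos3(x - tk1) * (tk - tj) / (tk - tk1)
            + pos3(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / norm
        cols.append(c)
    return np.column_stack(cols)


def nonlinearity_test(
    data: pd.DataFrame,
    term: str,
    terms: list[str] | None = None,
    knots: np.ndarray | None = None,
    n_knots: int = 4,
    **fit_kw,
) -> float:
    """Wald p that all nonlinear spline coefficients of ``term`` are zero."""
    terms = [t for t in (terms or []) if t != term]
    B = rcs_basis(data[term].to_numpy(), knots=knots, n_knots=n_knots)
    df = data.copy()
    names = [term] + [f"_rcs_{term}_{j}" for j in range(1, B.shape[1])]
    for j, name in enumerate(names):
        df[name] = B[:, j]
    model = fit_cox(df, names + terms, **fit_kw)
    idx = [model.terms.index(n) for n in names[1:]]
    b = model.beta[idx]
    V = model.cov[np.ix_(idx, idx)]
    W = float(b @ np.linalg.solve(V, b))
    return float(stats.chi2.sf(W, df=len(idx)))


def _age_interaction_fit(data, terms, term, entry_col, exit_col, event_col, ties):
    """Exact partial likelihood for the deterministic time-dependent
    covariate term * log(attained age); evaluated by a per-event-time pass
    (no cumulative trick applies because the covariate varies with t)."""
    entry = data[entry_col].to_numpy(float)
    exit_ = data[exit_col].to_numpy(float)
    event = data[event_col].to_numpy(bool)
    X = _design(data, terms)
    X = X - X.mean(axis=0)
    x = X[:, terms.index(term)]
    te = np.unique(exit_[event])
    p = X.shape[1] + 1

    def nll_grad_info(beta):
        b, g = beta[:-1], beta[-1]
        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        base = X @ b
        for t in te:
            at_risk = (entry < t) & (exit_ >= t)
            lt = np.log(t)
            eta = base[at_risk] + g * x[at_risk] * lt
            eta = eta - eta.max()
            r = np.exp(eta)
            Z = np.column_stack([X[at_risk], x[at_risk] * lt])
            S0 = r.sum()
            S1 = r @ Z
            S2 = (r[:, None] * Z).T @ Z
            dead = event[at_risk] & (exit_[at_risk] == t)
            d = dead.sum()
            # Breslow ties (continuous ages: d is almost always 1)
            ll += eta[dead].sum() - d * np.log(S0)
            mu = S1 / S0
            grad += Z[dead].sum(axis=0) - d * mu
            info += d * (S2 / S0 - np.outer(mu, mu))
        return ll, grad, info

    beta = np.zeros(p)
    for _ in range(50):
        ll, grad, info = nll_grad_info(beta)
        if np.abs(grad).max() < 1e-8:
            break
        beta = beta + np.linalg.solve(info, grad)
    cov = np.linalg.inv(info)
    se = np.sqrt(cov[-1, -1])
    zstat = beta[-1] / se
    return 2 * stats.norm.sf(abs(zstat))


def ph_diagnostics(
    model: HazardModel,
    data: pd.DataFrame,
    entry_col: str = "entry_age",
    exit_col: str = "exit_age",
    event_col: str = "event",
    age_interaction: bool = True,
    transform=None,
) -> dict:
    """Proportional-hazards diagnostics per model term.

    Scaled-Schoenfeld test: Grambsch-Therneau score statistic correlating
    each term's Schoenfeld residuals with event age g(t) (default identity).
    Optionally refits with a term x log(attained age) product (an exact
    deterministic time-dependent covariate) and reports its Wald p.
    """
    if model.n_events < 2:
        raise ValueError("PH diagnostics need >= 2 events")
    X = _design(data, model.terms)
    X = X - X.mean(axis=0)
    cd = _CoxData(data[entry_col], data[exit_col], data[event_col], X, model.ties)
    times, resid = cd.schoenfeld_residuals(model.beta)
    g = times if transform is None else transform(times)
    gc = g - g.mean()
    d = len(times)
    _, _, info = cd.loglik_grad_info(model.beta)
    z = gc @ resid  # (p,)
    var = float(gc @ gc) / d * np.diag(info)
    chi2 = z**2 / var
    schoenfeld_p = stats.chi2.sf(chi2, df=1)
    out = {
        "schoenfeld_p": dict(zip(model.terms, np.asarray(schoenfeld_p, float))),
        "schoenfeld_chi2": dict(zip(model.terms, np.asarray(chi2, float))),
    }
    if age_interaction:
        ages = {}
        for term in model.terms:
            ages[term] = float(
                _age_interaction_fit(
                    data, model.terms, term, entry_col, exit_col, event_col, model.ties
                )
            )
        out["age_interaction_p"] = ages
    return out


def interaction_test(
    data: pd.DataFrame,
    exposure: str,
    modifier: str,
    terms: list[str],
    method: str = "wald",
    **fit_kw,
) -> float:
    """Test effect modification via the exposure x modifier product term."""
    if data[modifier].nunique() < 2:
        raise ValueError(f"modifier {modifier!r} does not vary")
    df = data.copy()
    name = f"_ix_{exposure}_{modifier}"
    df[name] = df[exposure].astype(float) * df[modifier].astype(float)
    base_terms = list(dict.fromkeys([exposure, modifier] + list(terms)))
    full = fit_cox(df, base_terms + [name], **fit_kw)
    j = full.terms.index(name)
    if method == "wald":
        z = full.beta[j] / np.sqrt(full.cov[j, j])
        return float(2 * stats.norm.sf(abs(z)))
    if method == "lr":
        reduced = fit_cox(df, base_terms, **fit_kw)
        lr = 2 * (full.loglik - reduced.loglik)
        return float(stats.chi2.sf(max(lr, 0.0), df=1))
    raise ValueError(f"unknown method {method!r}")


def loglog_plot_data(
    data: pd.DataFrame,
    group_col: str,
    entry_col: str = "entry_age",
    exit_col: str = "exit_age",
    event_col: str = "event",
) -> pd.DataFrame:
    """log(-log S(t)) vs log t per group (Nelson-Aalen with left truncation).

    Emitted as plot data for visual PH assessment; not auto-judged.
    """
    rows = []
    for gval, sub in data.groupby(group_col):
        entry = sub[entry_col].to_numpy(float)
        exit_ = sub[exit_col].to_numpy(float)
        event = sub[event_col].to_numpy(bool)
        te = np.unique(exit_[event])
        H = 0.0
        for t in te:
            n_risk = int(((entry < t) & (exit_ >= t)).sum())
            d = int((event & (exit_ == t)).sum())
            if n_risk > 0:
                H += d / n_risk
            if H > 0:
                rows.append(
                    {
                        "group": gval,
                        "age": t,
                        "log_age": np.log(t),
                        "cum_hazard": H,
                        "loglog_survival": np.log(H),
                    }
                )
    return pd.DataFrame(rows)
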