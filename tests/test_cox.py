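"""Cox engine: oracle equivalence, invariances, cause classification,
contrasts, trend, splines, PH diagnostics, interactions."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from dietcal.cox import (
    ConvergenceError,
    classify_cause,
    contrast_hr,
    event_indicator,
    fit_cox,
    interaction_test,
    loglog_plot_data,
    nonlinearity_test,
    ph_diagnostics,
    rcs_basis,
    trend_test,
)
from conftest import weibull_survival_frame

# run the reference implementation to full convergence so it is a genuine
# oracle (its default stopping rules leave ~1e-5 in the coefficients)
LIFELINES_STRICT = {"precision": 1e-14, "r_precision": 0.0, "max_steps": 500}


class TestCauseClassifier:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("I00", "cvd"),
            ("I21", "cvd"),
            ("I78", "cvd"),
            ("I79", "other_natural"),
            ("C00", "cancer"),
            ("C97", "cancer"),
            ("C98", "other_natural"),
            ("V43", "unnatural_censor"),
            ("V43.2", "unnatural_censor"),
            ("U09", "unnatural_censor"),
            ("W19", "unnatural_censor"),
            ("X42", "unnatural_censor"),
            ("Y09", "unnatural_censor"),
            ("J18", "other_natural"),
            ("E11", "other_natural"),
        ],
    )
    def test_icd10_ranges(self, code, expected):
        assert classify_cause(code) == expected

    @pytest.mark.parametrize("bad", ["", "123", "I2", "ZZZ", "i21"])
    def test_malformed_codes_rejected(self, bad):
        with pytest.raises(ValueError, match="malformed"):
            classify_cause(bad)

    def test_cause_specific_censoring_semantics(self):
        death = np.array([1, 1, 1, 1, 0])
        codes = pd.Series(["I21", "C50", "J18", "V43", ""])
        assert event_indicator(death, codes, "all_cause").tolist() == [True, True, True, False, False]
        assert event_indicator(death, codes, "cvd").tolist() == [True, False, False, False, False]
        assert event_indicator(death, codes, "cancer").tolist() == [False, True, False, False, False]


def hand_partial_likelihood(beta, times, events, x):
    """Independent oracle: textbook partial likelihood, no ties, no
    truncation, written as an explicit double loop."""
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            riskset = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in riskset))
    return ll


class TestFitOracles:
    def test_grid_maximizer_toy(self):
        """1 covariate, 4 events: the engine's beta equals the brute-force
        grid (then golden-section) maximizer of the hand-written partial
        likelihood."""
        times = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0])
        events = np.array([1, 0, 1, 1, 0, 1], bool)
        x = np.array([0.5, -1.0, 1.5, 0.0, 2.0, -0.5])
        grid = np.linspace(-3, 3, 6001)
        lls = [hand_partial_likelihood(b, times, events, x) for b in grid]
        b0 = grid[int(np.argmax(lls))]
        res = optimize.minimize_scalar(
            lambda b: -hand_partial_likelihood(b, times, events, x),
            bracket=(b0 - 0.01, b0, b0 + 0.01),
            method="golden",
            options={"xtol": 1e-12},
        )
        df = pd.DataFrame(
            {"entry_age": 0.0, "exit_age": times, "event": events, "x": x}
        )
        m = fit_cox(df, ["x"])
        assert m.beta[0] == pytest.approx(res.x, abs=1e-6)

    def test_matches_lifelines_with_left_truncation(self, survival_frame):
        lifelines = pytest.importorskip("lifelines")
        m = fit_cox(survival_frame, ["x", "z"])
        cph = lifelines.CoxPHFitter()
        cph.fit(
            survival_frame,
            duration_col="exit_age",
            event_col="event",
            entry_col="entry_age",
            fit_options=dict(LIFELINES_STRICT),
        )
        np.testing.assert_allclose(m.beta, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(m.se, cph.standard_errors_.values, atol=1e-6)
        assert m.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_matches_lifelines_without_truncation(self):
        lifelines = pytest.importorskip("lifelines")
        df = weibull_survival_frame(n=200, seed=9, beta_x=0.5, beta_z=0.2)
        df["exit_age"] = df["exit_age"] - df["entry_age"]
        df["entry_age"] = 0.0
        m = fit_cox(df, ["x", "z"])
        cph = lifelines.CoxPHFitter()
        cph.fit(
            df[["exit_age", "event", "x", "z"]],
            duration_col="exit_age",
            event_col="event",
            fit_options=dict(LIFELINES_STRICT),
        )
        np.testing.assert_allclose(m.beta, cph.params_.values, atol=1e-6)
        assert m.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_matches_lifelines_efron_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        n = 150
        t = rng.integers(1, 15, n).astype(float)  # coarse times force ties
        df = pd.DataFrame(
            {
                "entry_age": 0.0,
                "exit_age": t,
                "event": rng.random(n) < 0.6,
                "x": rng.normal(size=n),
            }
        )
        m = fit_cox(df, ["x"], ties="efron")
        cph = lifelines.CoxPHFitter()
        cph.fit(
            df[["exit_age", "event", "x"]],
            duration_col="exit_age",
            event_col="event",
            fit_options=dict(LIFELINES_STRICT),
        )
        np.testing.assert_allclose(m.beta, cph.params_.values, atol=1e-6)


class TestFitContracts:
    def test_shift_invariance(self, survival_frame):
        m1 = fit_cox(survival_frame, ["x", "z"])
        df = survival_frame.copy()
        df["x"] = df["x"] + 100.0
        m2 = fit_cox(df, ["x", "z"])
        np.testing.assert_allclose(m1.beta, m2.beta, atol=1e-7)

    def test_rescale_equivariance(self, survival_frame):
        m1 = fit_cox(survival_frame, ["x", "z"])
        df = survival_frame.copy()
        df["x"] = df["x"] * 10.0
        m2 = fit_cox(df, ["x", "z"])
        assert m2.beta[0] == pytest.approx(m1.beta[0] / 10.0, rel=1e-6)

    def test_late_entrants_outside_risk_sets_are_inert(self, survival_frame):
        """Subjects entering after the last event age never join a risk set;
        dropping them must not change anything."""
        last_event = survival_frame.loc[survival_frame.event, "exit_age"].max()
        extra = pd.DataFrame(
            {
                "entry_age": [last_event + 1.0, last_event + 2.0],
                "exit_age": [last_event + 5.0, last_event + 6.0],
                "event": [False, False],
                "x": [3.0, -3.0],
                "z": [1.0, 0.0],
            }
        )
        m1 = fit_cox(survival_frame, ["x", "z"])
        m2 = fit_cox(pd.concat([survival_frame, extra], ignore_index=True), ["x", "z"])
        np.testing.assert_allclose(m1.beta, m2.beta, atol=1e-12)
        assert m1.loglik == pytest.approx(m2.loglik, abs=1e-12)

    def test_exit_before_entry_rejected(self):
        df = pd.DataFrame(
            {"entry_age": [50.0], "exit_age": [49.0], "event": [True], "x": [1.0]}
        )
        with pytest.raises(ValueError, match="exit age"):
            fit_cox(df, ["x"])

    def test_separation_detected(self):
        # perfectly separating covariate drives beta to infinity
        df = pd.DataFrame(
            {
                "entry_age": 0.0,
                "exit_age": np.concatenate([np.arange(1, 21), np.arange(21, 41)]).astype(float),
                "event": [True] * 20 + [False] * 20,
                "x": [1.0] * 20 + [0.0] * 20,
            }
        )
        with pytest.raises(ConvergenceError):
            fit_cox(df, ["x"])

    def test_constant_term_rejected(self, survival_frame):
        df = survival_frame.copy()
        df["c"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_cox(df, ["x", "c"])

    def test_null_wald_calibration_small(self):
        """Under beta = 0 truth the Wald p-values are ~uniform (coarse
        30-replicate screen; the full 500-replicate calibration runs with
        the acceptance checks)."""
        ps = []
        for seed in range(30):
            df = weibull_survival_frame(n=400, seed=100 + seed)
            ps.append(fit_cox(df, ["x"]).wald_p()[0])
        assert 0 <= np.mean(np.array(ps) < 0.05) <= 0.2
        assert stats.kstest(ps, "uniform").pvalue > 0.005


class TestContrasts:
    def test_constructed_inverse_hr(self, survival_frame):
        m = fit_cox(survival_frame, ["x", "z"])
        m.beta[0] = np.log(1.5) / np.log1p(46.5)
        c = contrast_hr(m, "x", 46.5, 0.0)
        assert c.hr == pytest.approx(1.5, rel=1e-12)

    def test_degenerate_contrast_rejected(self, survival_frame):
        m = fit_cox(survival_frame, ["x", "z"])
        with pytest.raises(ValueError, match="degenerate"):
            contrast_hr(m, "x", 5.0, 5.0)

    def test_ci_encloses_point(self, survival_frame):
        m = fit_cox(survival_frame, ["x", "z"])
        c = contrast_hr(m, "x", 46.5, 0.0)
        assert c.ci_low <= c.hr <= c.ci_high


class TestTrend:
    def test_monotone_effect_detected(self):
        """Simulated monotone hazard across intake quartiles: trend p is
        tiny at n = 20,000 (power ~1 for a top-quartile HR of 1.6)."""
        rng = np.random.default_rng(21)
        n = 20000
        medians = {0: 0.0, 1: 4.0, 2: 9.1, 3: 15.6, 4: 41.7}
        cat = rng.integers(0, 5, n)
        score = np.vectorize(medians.get)(cat)
        beta = np.log(1.6) / medians[4]
        entry = rng.uniform(40, 70, n)
        u = rng.random(n)
        T = 92.0 * ((entry / 92.0) ** 9 - np.log(u) / np.exp(beta * score)) ** (1 / 9)
        C = entry + rng.uniform(8, 14, n)
        df = pd.DataFrame(
            {
                "entry_age": entry,
                "exit_age": np.minimum(T, C),
                "event": T <= C,
                "cat": cat,
                "z": rng.normal(size=n),
            }
        )
        p = trend_test(df, "cat", medians, ["z"])
        assert p < 0.001

    def test_missing_category_median_rejected(self, survival_frame):
        df = survival_frame.copy()
        df["cat"] = np.arange(len(df)) % 5
        with pytest.raises(ValueError, match="medians"):
            trend_test(df, "cat", {0: 0.0, 1: 1.0}, ["z"])


class TestSplines:
    def test_basis_is_c2_continuous_with_linear_tails(self):
        knots = np.array([2.0, 4.0, 7.0, 9.0])
        h = 1e-5
        for k in knots:
            for col in range(3):
                pts = rcs_basis(np.array([k - 2 * h, k - h, k, k + h, k + 2 * h]), knots=knots)[:, col]
                d1l = (pts[2] - pts[0]) / (2 * h)
                d1r = (pts[4] - pts[2]) / (2 * h)
                assert d1r - d1l == pytest.approx(0.0, abs=1e-4)  # C1
                d2l = (pts[2] - 2 * pts[1] + pts[0]) / h**2
                d2r = (pts[4] - 2 * pts[3] + pts[2]) / h**2
                assert d2r - d2l == pytest.approx(0.0, abs=1e-2)  # C2
        # linear tails: second differences vanish beyond the boundary knots
        left = rcs_basis(np.array([-5.0, -4.0, -3.0]), knots=knots)
        right = rcs_basis(np.array([20.0, 21.0, 22.0]), knots=knots)
        for B in (left, right):
            assert np.abs(np.diff(B, n=2, axis=0)).max() < 1e-9

    def test_knots_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            rcs_basis(np.arange(30.0), knots=np.array([1.0, 1.0, 2.0, 3.0]))

    def test_needs_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            rcs_basis(np.repeat([1.0, 2.0], 10))

    def test_quadratic_hazard_detected(self):
        """A quadratic log-hazard in x is flagged by the 4-knot spline
        nonlinearity test at n = 20,000."""
        rng = np.random.default_rng(31)
        n = 20000
        entry = rng.uniform(40, 70, n)
        x = rng.normal(size=n)
        u = rng.random(n)
        T = 92.0 * ((entry / 92.0) ** 9 - np.log(u) / np.exp(0.12 * x**2)) ** (1 / 9)
        C = entry + rng.uniform(8, 14, n)
        df = pd.DataFrame(
            {"entry_age": entry, "exit_age": np.minimum(T, C), "event": T <= C, "x": x}
        )
        assert nonlinearity_test(df, "x") < 0.001

    def test_linear_hazard_not_flagged(self):
        df = weibull_survival_frame(n=8000, seed=41, beta_x=0.4)
        assert nonlinearity_test(df, "x", ["z"]) > 0.01


class TestPHDiagnostics:
    def test_schoenfeld_residuals_sum_to_zero(self, survival_frame):
        from dietcal.cox import _CoxData

        m = fit_cox(survival_frame, ["x", "z"])
        X = survival_frame[["x", "z"]].to_numpy(float)
        cd = _CoxData(
            survival_frame.entry_age,
            survival_frame.exit_age,
            survival_frame.event,
            X - X.mean(0),
            "efron",
        )
        _, resid = cd.schoenfeld_residuals(m.beta)
        np.testing.assert_allclose(resid.sum(axis=0), 0.0, atol=1e-8)

    def test_proportional_hazard_passes(self):
        df = weibull_survival_frame(n=4000, seed=51, beta_x=0.5)
        m = fit_cox(df, ["x", "z"])
        d = ph_diagnostics(m, df, age_interaction=True)
        assert d["schoenfeld_p"]["x"] > 0.01
        assert d["age_interaction_p"]["x"] > 0.01

    @staticmethod
    def _decaying_effect_frame(n, seed):
        """Discrete-hazard generator whose x effect decays with attained
        age: log HR = 0.8 at age 40 shrinking to 0 by age 90 (non-PH)."""
        rng = np.random.default_rng(seed)
        entry = rng.uniform(40, 60, n)
        x = rng.normal(size=n)
        ages = np.arange(40, 95)
        h0 = 0.002 * np.exp(0.09 * (ages - 40))
        alive = np.ones(n, bool)
        exit_age = np.minimum(entry + rng.uniform(8, 14, n), 94.0)
        death_age = np.full(n, np.inf)
        for a, h in zip(ages, h0):
            at_risk = alive & (entry <= a) & (a < exit_age)
            beta_t = 0.8 * np.clip((90 - a) / 50.0, 0, None)
            pdie = 1 - np.exp(-h * np.exp(beta_t * x[at_risk]))
            dies = rng.random(at_risk.sum()) < pdie
            idx = np.flatnonzero(at_risk)[dies]
            death_age[idx] = a + rng.random(len(idx))
            alive[idx] = False
        event = death_age < exit_age
        return pd.DataFrame(
            {
                "entry_age": entry,
                "exit_age": np.where(event, death_age, exit_age),
                "event": event,
                "x": x,
            }
        )

    def test_decaying_hazard_ratio_detected(self):
        df = self._decaying_effect_frame(20000, 61)
        m = fit_cox(df, ["x"])
        d = ph_diagnostics(m, df, age_interaction=True)
        assert d["schoenfeld_p"]["x"] < 0.01
        assert d["age_interaction_p"]["x"] < 0.01

    def test_loglog_plot_data_monotone(self, survival_frame):
        df = survival_frame.copy()
        df["grp"] = (df["x"] > 0).astype(int)
        pd_ = loglog_plot_data(df, "grp")
        for _, sub in pd_.groupby("group"):
            assert sub["cum_hazard"].is_monotonic_increasing


class TestInteractions:
    def test_modifier_must_vary(self, survival_frame):
        df = survival_frame.copy()
        df["w"] = 1.0
        with pytest.raises(ValueError, match="vary"):
            interaction_test(df, "x", "w", [])

    def test_sex_specific_effect_detected(self):
        """HR 1.0 in one stratum vs ~1.5 in the other is detected at n=30,000."""
        rng = np.random.default_rng(71)
        n = 30000
        entry = rng.uniform(40, 70, n)
        x = rng.normal(size=n)
        z = rng.binomial(1, 0.5, n).astype(float)
        beta = 0.4 * z  # effect only when z = 1
        u = rng.random(n)
        T = 92.0 * ((entry / 92.0) ** 9 - np.log(u) / np.exp(beta * x)) ** (1 / 9)
        C = entry + rng.uniform(8, 14, n)
        df = pd.DataFrame(
            {"entry_age": entry, "exit_age": np.minimum(T, C), "event": T <= C, "x": x, "z": z}
        )
        assert interaction_test(df, "x", "z", []) < 0.01

    def test_wald_and_lr_agree_first_order(self):
        df = weibull_survival_frame(n=12000, seed=81, beta_x=0.3, beta_z=0.2)
        pw = interaction_test(df, "x", "z", [], method="wald")
        pl = interaction_test(df, "x", "z", [], method="lr")
        assert abs(pw - pl) < 0.02
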