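"""Regression calibration, BCa bootstrap, validity deattenuation."""

import numpy as np
import pandas as pd
import pytest

from dietcal.calibration import (
    bca_endpoints,
    bootstrap_bca,
    calibrated_hazard_ratio,
    deattenuate_correlation,
    fit_calibration,
    predict_calibrated,
    CalibrationModel,
)
from dietcal.cox import contrast_hr, fit_cox
from dietcal.simulate import SimulationConfig, generate_dataset, generate_ffq_and_recalls, generate_true_exposures
from conftest import attenuation_config, weibull_survival_frame


def substudy_with_reliability(reliability, seed=0, n=1000, recall_sd=0.3):
    # draw from a 4x pool so the equal-race substudy allocation fills
    cfg = attenuation_config(seed, n=4 * n, reliability=reliability)
    cfg.substudy_size = n
    cfg.recall_error = recall_sd
    true = generate_true_exposures(cfg)
    _, sub = generate_ffq_and_recalls(true, cfg)
    return sub


class TestCalibrationModel:
    def test_zero_error_gives_identity(self):
        cfg = attenuation_config(1, n=800)
        cfg.substudy_size = 800
        cfg.ffq_error = 0.0
        cfg.recall_error = 0.0
        true = generate_true_exposures(cfg)
        _, sub = generate_ffq_and_recalls(true, cfg)
        cal = fit_calibration(sub, "unprocessed_red")
        assert cal.slope == pytest.approx(1.0, abs=1e-6)
        assert cal.intercept == pytest.approx(0.0, abs=1e-6)

    def test_reliability_half_gives_half_slope(self):
        cal = fit_calibration(substudy_with_reliability(0.5, seed=2), "unprocessed_red")
        assert cal.slope == pytest.approx(0.5, abs=0.08)
        assert cal.n == 1000

    def test_rank_deficiency_names_columns(self):
        sub = substudy_with_reliability(0.5, seed=3, n=200)
        sub["dup"] = sub["energy"]
        with pytest.raises(ValueError, match="collinear"):
            fit_calibration(sub, "unprocessed_red", ["energy", "dup"])

    def test_prediction_arithmetic(self):
        model = CalibrationModel(
            exposure="x", intercept=2.0, slope=0.5, covariate_coefs={},
            residual_variance=0.1, n=100, transform="identity",
        )
        df = pd.DataFrame({"x": [10.0]})
        assert predict_calibrated(df, model).iloc[0] == pytest.approx(7.0)

    def test_identity_model_is_passthrough(self):
        model = CalibrationModel(
            exposure="x", intercept=0.0, slope=1.0, covariate_coefs={},
            residual_variance=0.0, n=100, transform="identity",
        )
        df = pd.DataFrame({"x": np.linspace(0, 5, 7)})
        np.testing.assert_allclose(predict_calibrated(df, model), df["x"])

    def test_missing_covariate_rejected(self):
        model = CalibrationModel(
            exposure="x", intercept=0.0, slope=1.0, covariate_coefs={"z": 0.5},
            residual_variance=0.0, n=100, transform="identity",
        )
        df = pd.DataFrame({"x": [1.0, 2.0], "z": [1.0, np.nan]})
        with pytest.raises(ValueError, match="impute"):
            predict_calibrated(df, model)

    def test_shrinkage_reduces_variance(self):
        sub = substudy_with_reliability(0.4, seed=4)
        cal = fit_calibration(sub, "unprocessed_red")
        assert cal.slope < 1.0
        pred = predict_calibrated(sub, cal)
        assert pred.var() <= np.log1p(sub["ffq_unprocessed_red"]).var()


class TestCalibratedHazardRatio:
    def test_no_error_calibrated_equals_naive(self):
        cfg = attenuation_config(5, n=4000)
        cfg.ffq_error = 0.0
        cfg.recall_error = 0.0
        cfg.substudy_size = 1000
        cohort, sub, truth, tt = generate_dataset(cfg)
        cohort["event"] = cohort["death"].astype(bool)
        cohort["x"] = np.log1p(cohort["ffq_unprocessed_red"])
        naive = contrast_hr(fit_cox(cohort, ["x"]), "x", 46.5, 0.0)
        con, _, cal = calibrated_hazard_ratio(cohort, sub, "unprocessed_red", [], x1=46.5)
        assert cal.slope == pytest.approx(1.0, abs=1e-6)
        assert con.hr == pytest.approx(naive.hr, abs=1e-6)

    def test_calibrated_beta_is_naive_over_slope(self):
        cfg = attenuation_config(6, n=12000, reliability=0.5)
        cohort, sub, truth, tt = generate_dataset(cfg)
        cohort["event"] = cohort["death"].astype(bool)
        cohort["x"] = np.log1p(cohort["ffq_unprocessed_red"])
        naive_beta = fit_cox(cohort, ["x"]).beta[0]
        con, model, cal = calibrated_hazard_ratio(cohort, sub, "unprocessed_red", [], x1=46.5)
        assert model.beta[0] == pytest.approx(naive_beta / cal.slope, rel=1e-6)

    def test_calibration_equivariance_identity_scale(self):
        """Rescaling the error-prone exposure by c rescales the slope by
        1/c and leaves the calibrated contrast invariant (the calibrated
        variable lives on the unchanged reference scale)."""
        cfg = attenuation_config(7, n=4000, reliability=0.6)
        cohort, sub, truth, tt = generate_dataset(cfg)
        cohort["event"] = cohort["death"].astype(bool)
        con1, _, cal1 = calibrated_hazard_ratio(
            cohort, sub, "unprocessed_red", [], x1=46.5, transform="identity"
        )
        c = 10.0
        cohort2, sub2 = cohort.copy(), sub.copy()
        cohort2["ffq_unprocessed_red"] = cohort2["ffq_unprocessed_red"] * c
        sub2["ffq_unprocessed_red"] = sub2["ffq_unprocessed_red"] * c
        con2, _, cal2 = calibrated_hazard_ratio(
            cohort2, sub2, "unprocessed_red", [], x1=46.5, transform="identity"
        )
        assert cal2.slope == pytest.approx(cal1.slope / c, rel=1e-9)
        assert con2.hr == pytest.approx(con1.hr, rel=1e-9)

    def test_stage_failures_are_labelled(self):
        cohort = pd.DataFrame({"ffq_unprocessed_red": [1.0, 2.0]})
        with pytest.raises(RuntimeError, match="calibration stage"):
            calibrated_hazard_ratio(cohort, cohort, "unprocessed_red", [])


class TestBCa:
    def test_percentile_identity_when_unadjusted(self):
        rng = np.random.default_rng(0)
        reps = rng.normal(size=999)
        lo, hi = bca_endpoints(reps, z0=0.0, a=0.0, alpha=0.05)
        q = np.quantile(reps, [0.025, 0.975], method="linear")
        assert lo == q[0] and hi == q[1]

    def test_interval_deterministic_given_seed(self):
        data = {"d": pd.DataFrame({"v": np.random.default_rng(1).normal(size=60)})}
        stat = lambda d: float(d["v"].mean())
        b1 = bootstrap_bca(stat, data, B=300, seed=42)
        b2 = bootstrap_bca(stat, data, B=300, seed=42)
        assert b1.ci_low == b2.ci_low and b1.ci_high == b2.ci_high
        np.testing.assert_array_equal(b1.replicates, b2.replicates)

    def test_monotone_transformation_respected(self):
        """BCa endpoints of exp(statistic) agree with exp(endpoints of the
        statistic): z0 is exactly invariant and the jackknife acceleration
        nearly so, so the adjusted quantile levels coincide closely."""
        rng = np.random.default_rng(2)
        data = {"d": pd.DataFrame({"v": rng.normal(0.5, 0.2, 80)})}
        b_log = bootstrap_bca(lambda d: float(d["v"].mean()), data, B=2000, seed=5)
        b_exp = bootstrap_bca(lambda d: float(np.exp(d["v"].mean())), data, B=2000, seed=5)
        assert b_exp.z0 == b_log.z0
        assert np.exp(b_log.ci_low) == pytest.approx(b_exp.ci_low, rel=0.005)
        assert np.exp(b_log.ci_high) == pytest.approx(b_exp.ci_high, rel=0.005)

    def test_degenerate_statistic_warns_point_mass(self):
        data = {"d": pd.DataFrame({"v": np.ones(30)})}
        with pytest.warns(UserWarning, match="degenerate"):
            br = bootstrap_bca(lambda d: float(d["v"].mean()), data, B=200, seed=1)
        assert br.ci_low == br.ci_high == 1.0 and br.degenerate

    def test_small_B_rejected(self):
        data = {"d": pd.DataFrame({"v": np.arange(10.0)})}
        with pytest.raises(ValueError, match="B"):
            bootstrap_bca(lambda d: float(d["v"].mean()), data, B=50, seed=0)

    def test_excess_refit_failures_abort(self):
        data = {"d": pd.DataFrame({"v": np.arange(20.0)})}

        def flaky(d):
            # succeeds on the original sample, fails on (almost) every
            # with-replacement resample, which contains duplicates
            if d["v"].nunique() < 20:
                raise RuntimeError("singular refit")
            return float(d["v"].mean())

        with pytest.raises(RuntimeError, match="replicates failed"):
            bootstrap_bca(flaky, data, B=200, seed=3)

    def test_skewed_statistic_shifts_interval_right(self):
        # positive acceleration/bias on a right-skewed statistic moves the
        # BCa interval toward the percentile interval's upper side
        rng = np.random.default_rng(4)
        data = {"d": pd.DataFrame({"v": rng.lognormal(0, 1, 60)})}
        br = bootstrap_bca(lambda d: float(d["v"].var()), data, B=2000, seed=6)
        plo, phi = np.quantile(br.replicates, [0.025, 0.975])
        assert br.a > 0 and br.ci_low > plo and br.ci_high > phi


class TestDeattenuation:
    def test_zero_within_person_variance_is_identity(self):
        rng = np.random.default_rng(0)
        truth = rng.lognormal(2.0, 1.0, 400)
        ffq = truth * np.exp(rng.normal(0, 0.5, 400))
        recalls = np.tile(truth[:, None], (1, 6))
        res = deattenuate_correlation(ffq, recalls)
        assert res["lambda"] == pytest.approx(0.0, abs=1e-12)
        assert res["r_deattenuated"] == pytest.approx(res["r_observed"])

    def test_attenuation_monotone_in_replicates(self):
        sub = substudy_with_reliability(0.55, seed=8, recall_sd=0.6)
        ffq = sub["ffq_unprocessed_red"].to_numpy()
        R = sub[[f"recall_unprocessed_red_{j}" for j in range(1, 7)]].to_numpy()
        keep = ffq > 0
        r1 = np.corrcoef(np.log1p(ffq[keep]), np.log1p(R[keep, 0]))[0, 1]
        r6 = np.corrcoef(np.log1p(ffq[keep]), np.log1p(R[keep]).mean(axis=1))[0, 1]
        assert r1 < r6  # averaging recalls reduces attenuation

    def test_validity_recovery(self):
        """The deattenuated FFQ-recall correlation recovers the generator's
        configured truth (one-seed check; the replicate-averaged recovery
        at the study's 0.74 runs with the acceptance checks)."""
        cfg = attenuation_config(9, n=4000, reliability=0.74**2)
        cfg.substudy_size = 1000
        true = generate_true_exposures(cfg)
        _, sub = generate_ffq_and_recalls(true, cfg)
        R = sub[[f"recall_unprocessed_red_{j}" for j in range(1, 7)]].to_numpy()
        res = deattenuate_correlation(sub["ffq_unprocessed_red"], R)
        assert res["r_deattenuated"] == pytest.approx(0.74, abs=0.05)

    def test_needs_replicates_and_signal(self):
        with pytest.raises(ValueError, match="replicates"):
            deattenuate_correlation(np.arange(10.0), np.arange(10.0)[:, None])
        rng = np.random.default_rng(1)
        const = np.full((50, 4), 3.0) + rng.normal(0, 1.0, (50, 4))
        with pytest.raises(ValueError, match="between-person"):
            deattenuate_correlation(np.full(50, 2.0) + rng.normal(0, 0.1, 50), const)
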