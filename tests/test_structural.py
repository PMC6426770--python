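import numpy as np
import pytest

import quadmtmm as qm
from quadmtmm.structural import (
    build_ld_spec,
    build_lm_spec,
    factor_scores,
    ld_from_tmu,
    lm_from_tmu,
)
from quadmtmm.sem_core import FitResult
from quadmtmm.tmu_model import TmuEstimates


def make_tmu(means, cov, I=3, K=2):
    cov = np.asarray(cov, float)
    return TmuEstimates(
        I=I, K=K, loadings={}, intercepts={}, trait_means=np.asarray(means, float),
        trait_cov=cov, error_vars={}, error_covs={}, phi=np.nan, phi_se=np.nan,
    )


TABLE2_TMU = make_tmu([0.954, 0.977], [[0.759, 0.637], [0.637, 0.761]])


class TestLdFromTmu:
    def test_published_closed_form_values(self):
        ld = ld_from_tmu(TABLE2_TMU, reference_method=1)
        assert ld.b1 == pytest.approx(-0.16, abs=0.01)
        assert ld.var_m == pytest.approx(0.25, abs=0.01)
        assert ld.e_m == pytest.approx(0.02, abs=0.005)
        assert ld.corr_tm == pytest.approx(-0.28, abs=0.01)
        assert ld.var_z == pytest.approx(0.23, abs=0.005)
        assert ld.r2 == pytest.approx(0.08, abs=0.005)

    def test_identical_methods_degenerate(self):
        tmu = make_tmu([1.0, 1.0], [[0.5, 0.5], [0.5, 0.5]])
        ld = ld_from_tmu(tmu, 1)
        assert ld.e_m == 0.0 and ld.var_m == pytest.approx(0.0, abs=1e-14)

    def test_moments_match_simulated_latent_differences(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((2, 2))
        cov = a @ a.T + 0.3 * np.eye(2)
        means = rng.normal(1, 0.5, 2)
        tmu = make_tmu(means, cov)
        ld = ld_from_tmu(tmu, 1)
        draws = rng.multivariate_normal(means, cov, size=1_000_000)
        m = draws[:, 1] - draws[:, 0]
        assert ld.e_m == pytest.approx(m.mean(), abs=0.01)
        assert ld.var_m == pytest.approx(m.var(), abs=0.01)
        assert ld.cov_tm == pytest.approx(np.cov(draws[:, 0], m, bias=True)[0, 1], abs=0.01)

    def test_invariants_hold(self):
        ld = ld_from_tmu(TABLE2_TMU, 1)
        ld.validate()


class TestLmFromTmu:
    def test_published_residual_variance(self):
        lm = lm_from_tmu(TABLE2_TMU)
        assert lm.var_z == pytest.approx(0.06, abs=0.005)

    def test_quartering_identity_against_ld(self):
        ld = ld_from_tmu(TABLE2_TMU, 1)
        lm = lm_from_tmu(TABLE2_TMU)
        assert lm.var_m == pytest.approx(ld.var_m / 4, abs=1e-12)
        assert lm.var_m == pytest.approx(0.0615, abs=0.001)
        assert lm.e_m == pytest.approx(ld.e_m / 2, abs=1e-12)

    def test_symmetric_methods_force_zero_slope(self):
        tmu = make_tmu([1.0, 1.0], [[0.7, 0.4], [0.4, 0.7]])
        lm = lm_from_tmu(tmu)
        assert lm.b1 == 0.0

    def test_three_methods_rejected(self):
        tmu = make_tmu([0, 0, 0], np.eye(3), K=3)
        with pytest.raises(ValueError, match="exactly 2"):
            lm_from_tmu(tmu)


class TestDirectFits:
    def test_reference_method_is_required(self, table1):
        with pytest.raises(ValueError, match="reference"):
            qm.fit_linear_ld(table1)

    def test_published_slope_significant_negative(self, app_fits):
        ld, res = app_fits["ld"]
        assert ld.b1 == pytest.approx(-0.16, abs=0.02)
        z = ld.b1 / res.se["b1"]
        assert z < -4  # strongly significant, negative

    def test_lm_slope_and_intercept_not_significant(self, app_fits):
        lm, res = app_fits["lm"]
        assert abs(lm.b0 / res.se["b0"]) < 1.96
        assert abs(lm.b1 / res.se["b1"]) < 1.96
        assert lm.var_z / res.se["var_z"] > 1.96  # residual variance is

    def test_chi_square_identical_across_parameterizations(self, app_fits):
        chis = [app_fits[k][1].stats.chi_square for k in ("tmu", "ld", "lm")]
        lls = [app_fits[k][1].stats.log_likelihood for k in ("tmu", "ld", "lm")]
        assert max(chis) - min(chis) < 1e-6
        assert max(lls) - min(lls) < 1e-6

    def test_closed_form_map_equals_direct_fit(self, app_fits):
        tmu_est, _ = app_fits["tmu"]
        ld_direct, _ = app_fits["ld"]
        ld_mapped = ld_from_tmu(tmu_est, 1)
        for name in ("mean_t", "var_t", "b0", "b1", "var_z", "e_m", "var_m", "corr_tm"):
            assert getattr(ld_mapped, name) == pytest.approx(
                getattr(ld_direct, name), abs=1e-5), name
        lm_direct, _ = app_fits["lm"]
        lm_mapped = lm_from_tmu(tmu_est)
        for name in ("mean_t", "var_t", "b0", "b1", "var_z", "var_m"):
            assert getattr(lm_mapped, name) == pytest.approx(
                getattr(lm_direct, name), abs=1e-5), name

    def test_perfect_fit_synthetic_recovery(self):
        spec = build_ld_spec(3, 2, 1, "strong", "identical")
        values = {
            "lam_2": 1.2, "lam_3": 0.9, "alpha_2": 0.1, "alpha_3": -0.05,
            "mean_x": 1.0, "var_x": 0.7, "b0": 0.2, "b1": -0.3, "var_z": 0.2,
        }
        for i in (1, 2, 3):
            for m in (1, 2):
                values[f"theta_{i}_{m}"] = 0.12
            values[f"theta_cov_{i}_12"] = 0.04
        x0 = np.array([values[n] for n in spec.free_names])
        moments = spec.implied_moments(x0, n=400)
        params, res = qm.fit_linear_ld(moments, reference=1, error_pairs="identical")
        assert res.stats.chi_square == pytest.approx(0.0, abs=1e-6)
        assert params.b1 == pytest.approx(-0.3, abs=1e-5)
        assert params.var_z == pytest.approx(0.2, abs=1e-5)

    def test_symmetric_moments_give_zero_lm_slope(self):
        spec = build_lm_spec(3, 2, "strong")
        values = {
            "lam_2": 1.1, "lam_3": 0.95, "alpha_2": 0.0, "alpha_3": 0.0,
            "mean_x": 1.0, "var_x": 0.6, "b0": 0.0, "b1": 0.0, "var_z": 0.1,
        }
        for i in (1, 2, 3):
            for m in (1, 2):
                values[f"theta_{i}_{m}"] = 0.15
        x0 = np.array([values[n] for n in spec.free_names])
        moments = spec.implied_moments(x0, n=300)
        params, _ = qm.fit_linear_lm(moments)
        assert params.b1 == pytest.approx(0.0, abs=1e-6)

    def test_standardized_slope_equals_trait_method_correlation(self, app_fits):
        ld, _ = app_fits["ld"]
        std_b1 = ld.b1 * np.sqrt(ld.var_t / ld.var_m)
        assert std_b1 == pytest.approx(ld.corr_tm, abs=1e-10)


def _error_free_fit(spec, struct_values):
    """A FitResult stand-in at user-chosen parameters with near-zero error."""
    values = {"lam_2": 1.0, "lam_3": 1.0, "alpha_2": 0.0, "alpha_3": 0.0}
    values.update(struct_values)
    for i in (1, 2, 3):
        for m in (1, 2):
            values[f"theta_{i}_{m}"] = 1e-8
    x = np.array([values[n] for n in spec.free_names])
    return FitResult(
        spec=spec, theta=x, estimates=values, se={}, vcov=np.eye(len(x)),
        implied=spec.implied_moments(x, 10), moments=spec.implied_moments(x, 10),
        stats=None, gradient_norm=0.0, f_min=0.0,
    )


class TestFactorScores:
    def test_ld_difference_score_with_error_free_indicators(self):
        # true T1 = 1, T2 = 1.5 -> method score T2 - T1 = 0.5
        spec = build_ld_spec(3, 2, 1, "strong")
        res = _error_free_fit(spec, {"mean_x": 1.0, "var_x": 0.5, "b0": 0.0,
                                     "b1": 0.0, "var_z": 0.3})
        y = np.array([[1, 1, 1, 1.5, 1.5, 1.5]])
        table = qm.IndicatorTable(y, [(i, m) for m in (1, 2) for i in (1, 2, 3)])
        scores = factor_scores(res, table)
        assert scores["trait_score"][0] == pytest.approx(1.0, abs=1e-4)
        assert scores["method_score"][0] == pytest.approx(0.5, abs=1e-4)

    def test_lm_half_difference_and_trait_average(self):
        # mother 2, father 3 -> M2* = 0.5; mother 2.5, father 1.5 -> T = 2, -0.5
        spec = build_lm_spec(3, 2, "strong")
        res = _error_free_fit(spec, {"mean_x": 2.0, "var_x": 0.5, "b0": 0.0,
                                     "b1": 0.0, "var_z": 0.3})
        y = np.array([[2, 2, 2, 3, 3, 3], [2.5, 2.5, 2.5, 1.5, 1.5, 1.5]])
        table = qm.IndicatorTable(y, [(i, m) for m in (1, 2) for i in (1, 2, 3)])
        scores = factor_scores(res, table)
        assert scores["method_score"][0] == pytest.approx(0.5, abs=1e-4)
        assert scores["trait_score"][1] == pytest.approx(2.0, abs=1e-4)
        assert scores["method_score"][1] == pytest.approx(-0.5, abs=1e-4)

    def test_rows_with_missing_indicators_skipped(self):
        spec = build_ld_spec(3, 2, 1, "strong")
        res = _error_free_fit(spec, {"mean_x": 1.0, "var_x": 0.5, "b0": 0.0,
                                     "b1": 0.0, "var_z": 0.3})
        y = np.array([[1, 1, 1, 1.5, 1.5, 1.5], [1, np.nan, 1, 1, 1, 1]])
        table = qm.IndicatorTable(y, [(i, m) for m in (1, 2) for i in (1, 2, 3)])
        scores = factor_scores(res, table)
        assert list(scores["subject"]) == [0]
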