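import numpy as np
import pytest
from scipy import integrate, stats

import quadmtmm as qm
from quadmtmm.lms_quadratic import (
    QuadraticStructural,
    _conditional_pieces,
    marginal_loglik,
    quadrature_weights,
)
from quadmtmm.data_io import IndicatorTable
from quadmtmm.simulate import SimulationDesign, application_population

from conftest import LOADINGS, INTERCEPTS, ld_quadratic_population, lm_quadratic_population

THETA = np.diag([0.2, 0.2, 0.2, 0.25, 0.25, 0.25])
LAYOUT = [(i, m) for m in (1, 2) for i in (1, 2, 3)]


def small_table(n=100, seed=7, struct=None):
    struct = struct or ld_quadratic_population()
    design = SimulationDesign(structural=struct, n=max(n, 50), replications=1,
                              reliability=0.8, master_seed=seed)
    table = qm.simulate_dataset(design, 0)
    return IndicatorTable(table.values[:n], table.layout)


class TestMarginalLoglik:
    @pytest.mark.parametrize("n_nodes", [2, 3, 8, 32])
    def test_linear_case_equals_closed_form(self, n_nodes):
        """With b2 = 0 the mixture collapses to one Gaussian exactly."""
        table = small_table(100)
        s = QuadraticStructural(0.18, -0.16, 0.0, 0.23, 0.95, 0.69, "ld", 1)
        _, m0, m1, _, _, sc = _conditional_pieces(LOADINGS, INTERCEPTS, THETA, s)
        mu = m0 + m1 * s.mean_x
        sigma = sc + s.var_x * np.outer(m1, m1)
        closed = stats.multivariate_normal(mu, sigma).logpdf(table.sorted().values).sum()
        ml = marginal_loglik(LOADINGS, INTERCEPTS, THETA, s, table, n_nodes)
        assert ml == pytest.approx(closed, abs=1e-8)

    @pytest.mark.parametrize("variant_struct", [ld_quadratic_population(), lm_quadratic_population()])
    def test_matches_brute_force_integration(self, variant_struct):
        """Quadrature equals adaptive 1-D integration of the same integrand."""
        table = small_table(20, struct=ld_quadratic_population())
        s = variant_struct
        _, m0, m1, m2, _, sc = _conditional_pieces(LOADINGS, INTERCEPTS, THETA, s)
        sinv = np.linalg.inv(sc)
        _, logdet = np.linalg.slogdet(sc)

        def integrand(t, y):
            d = y - (m0 + m1 * t + m2 * t * t)
            return np.exp(-0.5 * (6 * np.log(2 * np.pi) + logdet + d @ sinv @ d)) \
                * stats.norm.pdf(t, s.mean_x, np.sqrt(s.var_x))

        brute = 0.0
        for row in table.values:
            val, _ = integrate.quad(integrand, -12, 14, args=(row,),
                                    limit=200, epsabs=1e-14, epsrel=1e-12)
            brute += np.log(val)
        ml = marginal_loglik(LOADINGS, INTERCEPTS, THETA, s, table, 32)
        assert ml == pytest.approx(brute, abs=1e-6)

    def test_node_doubling_converged(self):
        table = small_table(50)
        s = ld_quadratic_population()
        ll24 = marginal_loglik(LOADINGS, INTERCEPTS, THETA, s, table, 24)
        ll48 = marginal_loglik(LOADINGS, INTERCEPTS, THETA, s, table, 48)
        assert abs(ll48 - ll24) < 1e-6

    def test_weights_sum_to_one(self):
        for n in (2, 8, 32, 64):
            _, w = quadrature_weights(n)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_minimum_node_count_enforced(self):
        with pytest.raises(ValueError):
            quadrature_weights(1)


class TestFitQuadratic:
    def test_moment_summary_rejected(self, table1):
        with pytest.raises(TypeError, match="raw data"):
            qm.fit_quadratic_ld(table1, reference=1)

    def test_fixed_zero_b2_matches_linear_fit(self, small_ld_table):
        fit = qm.fit_quadratic_ld(small_ld_table, reference=1, fix_b2=0.0,
                                  compute_se=False)
        lin, lin_res = qm.fit_linear_ld(small_ld_table, reference=1)
        assert fit.structural.b1 == pytest.approx(lin.b1, abs=1e-4)
        assert fit.structural.b0 == pytest.approx(lin.b0, abs=1e-4)
        assert fit.structural.var_z == pytest.approx(lin.var_z, abs=1e-4)
        assert fit.loglik == pytest.approx(lin_res.stats.log_likelihood, abs=1e-4)

    def test_fixed_zero_b2_matches_linear_lm_fit(self, small_ld_table):
        fit = qm.fit_quadratic_lm(small_ld_table, fix_b2=0.0, compute_se=False)
        lin, lin_res = qm.fit_linear_lm(small_ld_table)
        assert fit.structural.b1 == pytest.approx(lin.b1, abs=1e-4)
        assert fit.loglik == pytest.approx(lin_res.stats.log_likelihood, abs=1e-4)

    def test_freeing_b2_never_hurts_loglik(self, small_ld_table):
        fit = qm.fit_quadratic_ld(small_ld_table, reference=1, compute_se=False)
        assert fit.loglik >= fit.linear_loglik - 1e-6
        assert fit.lr_statistic >= 0.0

    def test_ld_and_lm_quadratic_fits_differ(self):
        """Quadratic LD and LM are no longer reparameterizations."""
        table = small_table(400, seed=21)
        ld = qm.fit_quadratic_ld(table, reference=1, compute_se=False)
        lm = qm.fit_quadratic_lm(table, compute_se=False)
        assert abs(ld.loglik - lm.loglik) > 0.01

    def test_null_calibration_and_pvalue_uniformity(self):
        """b2 = 0 population: LR p-values near-uniform, ~5% rejections."""
        design = SimulationDesign(
            structural=application_population("ld", "null"), n=300,
            replications=1, reliability=0.8, master_seed=1234,
        )
        pvals = []
        for rep in range(150):
            table = qm.simulate_dataset(design, rep)
            fit = qm.fit_quadratic_ld(table, reference=1, compute_se=False)
            pvals.append(fit.lr_p_value)
        pvals = np.array(pvals)
        rate = np.mean(pvals < 0.05)
        assert 0.005 <= rate <= 0.11
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_wald_ci_coverage_for_b2(self):
        """95% Wald intervals for b2 cover the truth at ~nominal rate."""
        b2_true, _ = qm.effect_size_to_beta2("large", 0.95, 0.69, 0.23)
        struct = QuadraticStructural(0.24, -0.33, b2_true, 0.23, 0.95, 0.69, "ld", 1)
        design = SimulationDesign(structural=struct, n=1000, replications=1,
                                  reliability=0.8, master_seed=555)
        covered = total = 0
        for rep in range(100):
            table = qm.simulate_dataset(design, rep)
            fit = qm.fit_quadratic_ld(table, reference=1, compute_se=True)
            if not fit.converged or not np.isfinite(fit.b2_se):
                continue
            total += 1
            covered += abs(fit.b2 - b2_true) <= 1.96 * fit.b2_se
        assert total >= 90
        assert 0.88 <= covered / total <= 0.995


class TestQuadFactorScores:
    def test_error_free_scores_recover_latent_difference(self):
        # nearly error-free indicators: posterior means hit the truth
        struct = QuadraticStructural(0.0, 0.0, 0.0, 0.3, 1.0, 0.5, "ld", 1)
        fit = qm.QuadFitResult(
            variant="ld", reference=1, loadings=np.ones(3), intercepts=np.zeros(3),
            error_cov=np.eye(6) * 1e-8, structural=struct, loglik=0.0, n_nodes=32,
            linear_loglik=0.0, lr_statistic=0.0, lr_p_value=1.0, converged=True,
            heywood=False, n_iter=0,
        )
        y = np.array([[1, 1, 1, 1.5, 1.5, 1.5]])
        table = IndicatorTable(y, LAYOUT)
        scores = qm.quad_factor_scores(fit, table)
        assert scores["trait_score"][0] == pytest.approx(1.0, abs=1e-3)
        assert scores["method_score"][0] == pytest.approx(0.5, abs=1e-3)
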