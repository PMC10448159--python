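import dataclasses

import numpy as np
import pytest

import triphase as tp
from conftest import zero_noise


@pytest.fixture(scope="module")
def small_fit(small_world):
    spec, params, designs = small_world
    chain = tp.fit_chain(tp.generate_responses(designs, params, 17), designs)
    return spec, params, designs, chain


class TestCovCoeffBlocks:
    def test_scalar_error_variance(self):
        G = np.array([[0.5, 0.1], [0.1, 0.3]])
        np.testing.assert_allclose(tp.cov_coeff_blocks(G, 4.0), 4.0 * G)
        np.testing.assert_allclose(tp.cov_coeff_blocks(np.eye(2), 9.0), 9.0 * np.eye(2))
        assert np.all(tp.cov_coeff_blocks(G, 0.0) == 0)

    def test_matrix_contraction(self):
        G = np.array([[0.5, 0.1], [0.1, 0.3]])
        E = np.array([[2.0, 0.5], [0.5, 1.0]])
        v = np.array([1.0, -2.0])
        np.testing.assert_allclose(
            tp.cov_coeff_blocks(G, E, v), float(v @ E @ v) * G
        )

    def test_rejects_indefinite_input(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            tp.cov_coeff_blocks(np.array([[1.0, 2.0], [2.0, 1.0]]), 1.0)

    def test_matches_brute_force_refits(self):
        """omega^2 (X'X)^-1 equals the empirical covariance of beta_hat
        over many refits with fresh noise (MC oracle)."""
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(12), rng.normal(2.0, 1.5, 12)])
        omega2, R = 4.0, 40_000
        G = tp.gram_inverse(X)
        H = G @ X.T
        betas = H @ rng.normal(0, np.sqrt(omega2), (12, R))  # noise-only responses
        emp = np.cov(betas)
        ana = tp.cov_coeff_blocks(G, omega2)
        scale = np.sqrt(np.outer(np.diag(ana), np.diag(ana)))
        assert np.abs((emp - ana) / scale).max() < 5 * np.sqrt(2 / R) * 3


class TestCovGammaDecomposition:
    def test_zero_noise_gives_zero_covariance(self, small_world):
        spec, params, designs = small_world
        parts = tp.cov_gamma_from_params(zero_noise(params), designs)
        assert np.all(parts.total(True) == 0)

    def test_field_noise_only_reduces_to_projected_field_covariance(self, small_world):
        """With delta^2 = theta^2 = 0 only the field-fit term survives:
        Cov(gamma_hat) = Gamma* A* Cov_F(beta_hat) A*' Gamma*'."""
        spec, params, designs = small_world
        z = np.zeros((2, 2))
        p = dataclasses.replace(params, Delta_star=z, delta2=0.0, Theta_star=z, theta2=0.0)
        parts = tp.cov_gamma_from_params(p, designs)
        GA = p.Gamma_star @ p.A_star
        expected = GA @ (p.omega2 * tp.gram_inverse(designs.X_I)) @ GA.T
        np.testing.assert_allclose(parts.total(True), expected, rtol=1e-12)
        assert np.all(parts.trace_alpha_level == 0)
        assert np.all(parts.trace_gamma_level == 0)

    def test_matches_empirical_covariance_quick(self, small_world):
        """Analytic Cov(gamma_hat) tracks the empirical covariance over
        refits (coarse check; the high-replication oracle lives in the
        acceptance suite)."""
        spec, params, designs = small_world
        R = 4000
        gs = np.empty((R, 2))
        for i in range(R):
            data = tp.generate_responses(
                designs, params, np.random.SeedSequence(21, spawn_key=(i,))
            )
            gs[i] = tp.fit_chain(data, designs).gamma_hat
        emp = np.cov(gs.T)
        ana = tp.cov_gamma_from_params(params, designs).total(True)
        q = designs.p_bar_U
        assert float(q @ emp @ q) == pytest.approx(float(q @ ana @ q), rel=0.12)


class TestVarianceReports:
    def test_full_minus_approx_equals_trace_sum(self, small_world):
        spec, params, designs = small_world
        parts = tp.cov_gamma_from_params(params, designs)
        full = tp.variance_3phmb(parts, designs.p_bar_U, include_traces=True)
        approx = tp.variance_3phmb(parts, designs.p_bar_U, include_traces=False)
        assert full.total - approx.total == pytest.approx(
            full.trace_alpha_level + full.trace_gamma_level, rel=1e-12
        )
        assert full.total == pytest.approx(
            full.term_Q + full.term_G + full.term_F + full.trace_terms, rel=1e-12
        )

    def test_terms_positive_for_noisy_world(self, small_world):
        spec, params, designs = small_world
        parts = tp.cov_gamma_from_params(params, designs)
        rep = tp.variance_3phhy(parts, params.gamma, designs.P_U, spec.n_IV)
        for term in (rep.term_Q, rep.term_G, rep.term_F, rep.design_term, rep.total):
            assert term > 0
        assert rep.trace_terms >= 0

    def test_census_collapses_design_term(self, small_world):
        """fpc = 0: the hybrid variance reduces to the model-based one."""
        spec, params, designs = small_world
        parts = tp.cov_gamma_from_params(params, designs)
        hy = tp.variance_3phhy(parts, params.gamma, designs.P_U, n_IV=spec.N)
        mb = tp.variance_3phmb(parts, designs.p_bar_U)
        assert hy.design_term == 0
        assert hy.trace_design == 0
        assert hy.total == pytest.approx(mb.total, rel=1e-12)

    def test_intercept_only_gamma_kills_design_term(self, small_world):
        spec, params, designs = small_world
        parts = tp.cov_gamma_from_params(params, designs)
        rep = tp.variance_3phhy(parts, np.array([5.0, 0.0]), designs.P_U, spec.n_IV)
        assert rep.design_term == pytest.approx(0.0, abs=1e-12)

    def test_oversized_sample_rejected(self, small_world):
        spec, params, designs = small_world
        parts = tp.cov_gamma_from_params(params, designs)
        with pytest.raises(ValueError, match="exceeds"):
            tp.variance_3phhy(parts, params.gamma, designs.P_U, n_IV=spec.N + 1)


class TestEstimateVariance:
    def test_noise_free_estimate_is_zero(self, small_world):
        spec, params, designs = small_world
        chain = tp.fit_chain(tp.generate_responses(designs, zero_noise(params), 0), designs)
        rep = tp.estimate_variance(chain, "3phmb", p_bar_U=designs.p_bar_U)
        assert rep.total == pytest.approx(0.0, abs=1e-15)

    def test_hybrid_estimator_runs_and_is_positive(self, small_fit):
        spec, params, designs, chain = small_fit
        sample = tp.draw_srswor(spec.N, spec.n_IV, 2)
        rep = tp.estimate_variance(
            chain, "3phhy", p_sample=designs.P_U[sample.indices], N=spec.N
        )
        assert rep.total > 0
        assert rep.design_term > 0

    def test_requires_mode_inputs(self, small_fit):
        spec, params, designs, chain = small_fit
        with pytest.raises(ValueError, match="p_bar_U"):
            tp.estimate_variance(chain, "3phmb")
        with pytest.raises(ValueError, match="p_sample"):
            tp.estimate_variance(chain, "3phhy")


class TestMSE:
    def test_addon_formula_true_and_plugin(self, small_fit):
        spec, params, designs, chain = small_fit
        rep = tp.estimate_variance(chain, "3phmb", p_bar_U=designs.p_bar_U)
        mse = tp.mse_under_independence(rep, params, spec.N)
        addon = (params.theta2 + params.delta2 + params.omega2) / spec.N
        assert mse == pytest.approx(rep.total + addon, rel=1e-12)
        mse_hat = tp.mse_under_independence(rep, chain, spec.N)
        addon_hat = (chain.theta2_hat + chain.delta2_hat + chain.omega2_hat) / spec.N
        assert mse_hat == pytest.approx(rep.total + addon_hat, rel=1e-12)

    def test_addon_vanishes_for_large_population(self, small_fit):
        spec, params, designs, chain = small_fit
        rep = tp.estimate_variance(chain, "3phmb", p_bar_U=designs.p_bar_U)
        assert tp.mse_under_independence(rep, params, 10**12) == pytest.approx(
            rep.total, rel=1e-9
        )

    def test_zero_noise_mse_equals_variance(self, small_world):
        spec, params, designs = small_world
        quiet = zero_noise(params)
        chain = tp.fit_chain(tp.generate_responses(designs, quiet, 0), designs)
        rep = tp.estimate_variance(chain, "3phmb", p_bar_U=designs.p_bar_U)
        assert tp.mse_under_independence(rep, quiet, spec.N) == pytest.approx(
            rep.total, abs=1e-15
        )
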