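"""Closed-form oracles for every Gibbs full conditional, plus priors."""

import numpy as np
import pandas as pd
import pytest

from mbgp._kernels import update_block_effects
from mbgp.bayes import (McmcConfig, build_priors, compute_gebv,
                        impute_missing_residuals, inv_wishart_batch,
                        inv_wishart_rvs, sample_block_covariance,
                        sample_fixed_effects, sample_residual_covariance)
from mbgp.types import BlockMap, PhenotypeTable

from conftest import make_panel, random_panel, stacked_pheno


class TestPriors:
    def _fixture(self):
        # 10 blocks x 10 SNPs, every allele frequency exactly 0.5 so each
        # block has sum 2 p q = 5; per-breed phenotypic variance exactly 1
        d = np.tile([0, 2, 1, 1, 0, 2], (100, 1)).T.astype(np.int8)
        panel = make_panel(d, breeds=["X"] * 3 + ["Y"] * 3)
        pheno = stacked_pheno(panel, [-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        table = pd.DataFrame({"chrom": "1",
                              "start": np.arange(0, 100, 10),
                              "stop": np.arange(10, 110, 10)})
        return panel, pheno, BlockMap(table)

    def test_degrees_of_freedom(self):
        panel, pheno, blocks = self._fixture()
        priors = build_priors(pheno, panel, blocks)
        assert priors.p == 2
        assert priors.df == 6.0

    def test_block_scale_worked_example(self):
        # h2 = 0.5, P = I, s = 10, df = 6, sum 2pq = 5 -> B_i = 0.002 I
        panel, pheno, blocks = self._fixture()
        priors = build_priors(pheno, panel, blocks, h2_prior=0.5)
        np.testing.assert_allclose(priors.P, np.eye(2), atol=1e-12)
        for i in range(10):
            np.testing.assert_allclose(priors.B[i], 0.002 * np.eye(2),
                                       atol=1e-12)

    def test_residual_scale_worked_example(self):
        # R_p = (1 - 0.5) I / 5 = 0.1 I
        panel, pheno, blocks = self._fixture()
        priors = build_priors(pheno, panel, blocks, h2_prior=0.5)
        np.testing.assert_allclose(priors.R_p, 0.1 * np.eye(2),
                                   atol=1e-12)

    def test_zero_phenotypic_variance_rejected(self):
        panel, pheno, blocks = self._fixture()
        flat = stacked_pheno(panel, [1.0, 1.0, 1.0, -1, 0, 1])
        with pytest.raises(ValueError, match="zero phenotypic variance"):
            build_priors(flat, panel, blocks)


class TestFixedEffectConditional:
    def test_single_breed_intercept_posterior_mean_is_mean(self, rng):
        y = rng.standard_normal((20, 1))
        X = np.ones((20, 1))
        mean, _ = sample_fixed_effects(X, y, np.eye(1), None)
        np.testing.assert_allclose(mean[0, 0], y.mean(), atol=1e-12)

    def test_matches_dense_gls_oracle(self, rng):
        # 2 breeds, n = 6, intercept + sex, dense-oracle GLS solution
        n, p = 6, 2
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)]).astype(float)
        ystar = rng.standard_normal((n, p))
        A = rng.standard_normal((p, p))
        R0 = A @ A.T + p * np.eye(p)
        mean, _ = sample_fixed_effects(X, ystar, R0, None)
        # oracle: full GLS on the trait-major stacked system
        Xbig = np.kron(np.eye(p), X)
        Rbig = np.kron(R0, np.eye(n))
        ybig = ystar.T.reshape(-1)
        Ri = np.linalg.inv(Rbig)
        beta = np.linalg.solve(Xbig.T @ Ri @ Xbig, Xbig.T @ Ri @ ybig)
        np.testing.assert_allclose(mean.T.reshape(-1), beta, atol=1e-10)

    def test_zero_response_zero_mean(self, rng):
        X = np.column_stack([np.ones(8), rng.standard_normal(8)])
        mean, _ = sample_fixed_effects(X, np.zeros((8, 2)), np.eye(2), None)
        np.testing.assert_allclose(mean, 0.0, atol=1e-14)

    def test_rank_deficient_design_names_column(self, rng):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="aliased"):
            sample_fixed_effects(X, rng.standard_normal((6, 1)), np.eye(1),
                                 None, names=["intercept", "dup"])

    def test_draw_distribution(self, rng):
        # draws scatter around the GLS mean with covariance kron(R0, XtX^-1)
        X = np.ones((50, 1))
        ystar = rng.standard_normal((50, 2))
        R0 = np.array([[1.0, 0.5], [0.5, 2.0]])
        draws = np.array([
            sample_fixed_effects(X, ystar, R0, rng)[1][0] for _ in range(4000)
        ])
        mean, _ = sample_fixed_effects(X, ystar, R0, None)
        np.testing.assert_allclose(draws.mean(axis=0), mean[0], atol=0.05)
        np.testing.assert_allclose(np.cov(draws.T), R0 / 50, atol=0.01)


class TestBlockEffectConditional:
    def _single_snp_mean(self, m, ydag, sigma_e2, sigma_a2):
        """Scalar ridge oracle for one SNP, one trait."""
        return (m @ ydag / sigma_e2) / (m @ m / sigma_e2 + 1 / sigma_a2)

    def test_scalar_ridge_oracle(self):
        m = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        ydag = np.array([0.3, -0.1, 0.8, 0.4, -0.2])
        E = ydag[:, None].copy()
        a = np.zeros((1, 1))
        bad = update_block_effects(
            E, np.asfortranarray(m[:, None]), np.array([m @ m]), a,
            np.eye(1), np.array([[1 / 0.5]]), np.zeros((1, 1)))
        assert bad == -1
        np.testing.assert_allclose(a[0, 0],
                                   self._single_snp_mean(m, ydag, 1.0, 0.5),
                                   atol=1e-12)
        # residuals updated incrementally
        np.testing.assert_allclose(E[:, 0], ydag - m * a[0, 0], atol=1e-12)

    def test_flat_prior_limit_is_ols(self, rng):
        m = rng.standard_normal(30)
        ydag = 0.4 * m + rng.standard_normal(30)
        E = ydag[:, None].copy()
        a = np.zeros((1, 1))
        update_block_effects(
            E, np.asfortranarray(m[:, None]), np.array([m @ m]), a,
            np.eye(1), np.array([[1e-6]]), np.zeros((1, 1)))
        ols = m @ ydag / (m @ m)
        np.testing.assert_allclose(a[0, 0], ols, rtol=1e-4)

    def test_zero_adjusted_response_zero_mean(self, rng):
        M = np.asfortranarray(rng.standard_normal((12, 4)))
        a = np.zeros((4, 2))
        E = np.zeros((12, 2))
        update_block_effects(E, M, np.einsum("ij,ij->j", M, M), a,
                             np.eye(2), np.eye(2) * 10, np.zeros((4, 2)))
        np.testing.assert_allclose(a, 0.0, atol=1e-14)

    def test_multitrait_conditional_matches_dense_oracle(self, rng):
        # p = 2 single-SNP conditional mean: (m'm R0^-1 + G^-1)^-1 R0^-1 E'm
        n = 15
        m = rng.standard_normal(n)
        E0 = rng.standard_normal((n, 2))
        R0 = np.array([[1.0, 0.4], [0.4, 0.8]])
        G = np.array([[0.5, 0.2], [0.2, 0.4]])
        R0inv, Ginv = np.linalg.inv(R0), np.linalg.inv(G)
        expected = np.linalg.solve(m @ m * R0inv + Ginv,
                                   R0inv @ (E0.T @ m))
        E = E0.copy()
        a = np.zeros((1, 2))
        update_block_effects(E, np.asfortranarray(m[:, None]),
                             np.array([m @ m]), a, R0inv, Ginv,
                             np.zeros((1, 2)))
        np.testing.assert_allclose(a[0], expected, atol=1e-12)


class TestCovarianceConditionals:
    def test_block_posterior_df_via_mc_mean(self, rng):
        # p = 2, m_i = 10 -> posterior df 16; MC mean ~ S/(nu - p - 1)
        a = rng.standard_normal((10, 2)) * 0.3
        B_i = np.array([[0.02, 0.005], [0.005, 0.03]])
        S = a.T @ a + B_i
        nu = 6.0 + 10
        n_mc = 200_000
        draws = inv_wishart_batch(np.full(n_mc, nu),
                                  np.repeat(S[None], n_mc, axis=0), rng)
        expected = S / (nu - 2 - 1)
        se = draws.std(axis=0) / np.sqrt(n_mc)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se)

    def test_zero_effects_reduce_to_prior_scale(self, rng):
        B_i = np.array([[0.5, 0.1], [0.1, 0.4]])
        state = rng.bit_generator.state
        g1 = sample_block_covariance(np.zeros((7, 2)), B_i, 6.0, rng)
        rng.bit_generator.state = state
        g2 = inv_wishart_rvs(6.0 + 7, B_i, rng)
        np.testing.assert_allclose(g1, g2, atol=1e-14)

    def test_residual_posterior_mc_mean(self, rng):
        E = rng.standard_normal((100, 2))
        R_p = np.eye(2) * 0.1
        S = E.T @ E + R_p
        nu = 6.0 + 100
        n_mc = 200_000
        draws = inv_wishart_batch(np.full(n_mc, nu),
                                  np.repeat(S[None], n_mc, axis=0), rng)
        expected = S / (nu - 3)
        se = draws.std(axis=0) / np.sqrt(n_mc)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se)

    def test_zero_residuals_reduce_to_prior(self, rng):
        R_p = np.array([[0.3, 0.0], [0.0, 0.2]])
        state = rng.bit_generator.state
        r1 = sample_residual_covariance(np.zeros((50, 2)), R_p, 6.0, rng)
        rng.bit_generator.state = state
        r2 = inv_wishart_rvs(56.0, R_p, rng)
        np.testing.assert_allclose(r1, r2, atol=1e-14)

    def test_diagonal_restriction_matches_univariate(self, rng):
        E = rng.standard_normal((40, 2))
        R_p = np.diag([0.3, 0.2])
        state = rng.bit_generator.state
        r = sample_residual_covariance(E, R_p, 6.0, rng, diagonal=True)
        assert r[0, 1] == 0.0 and r[1, 0] == 0.0
        rng.bit_generator.state = state
        scale = np.einsum("ij,ij->j", E, E) + np.diag(R_p)
        both = inv_wishart_batch(np.full(2, 46.0), scale[:, None, None],
                                 rng)
        np.testing.assert_allclose(np.diag(r), both[:, 0, 0], atol=1e-14)

    def test_iw_matches_scipy_marginals(self, rng):
        from scipy import stats
        S = np.array([[2.0, 0.7], [0.7, 1.5]])
        nu = 8.0
        ours = inv_wishart_batch(np.full(30_000, nu),
                                 np.repeat(S[None], 30_000, axis=0), rng)
        ref = stats.invwishart(df=nu, scale=S).rvs(size=30_000,
                                                   random_state=12)
        for idx in [(0, 0), (0, 1), (1, 1)]:
            ks = stats.ks_2samp(ours[:, idx[0], idx[1]],
                                ref[:, idx[0], idx[1]])
            assert ks.pvalue > 1e-3


class TestImputation:
    def test_diagonal_r0_no_borrowing(self, rng):
        E = np.zeros((2000, 2))
        E[:, 0] = 1.5  # observed residuals
        obs = np.zeros((2000, 2), dtype=bool)
        obs[:, 0] = True
        impute_missing_residuals(E, obs, np.diag([1.0, 2.0]), rng)
        assert abs(E[:, 1].mean()) < 3 * np.sqrt(2.0 / 2000)

    def test_bivariate_conditional_oracle(self, rng):
        # rho = 0.6, e1 = 1.5 -> conditional mean 0.9, variance 0.64
        n = 200_000
        E = np.zeros((n, 2))
        E[:, 0] = 1.5
        obs = np.zeros((n, 2), dtype=bool)
        obs[:, 0] = True
        R0 = np.array([[1.0, 0.6], [0.6, 1.0]])
        impute_missing_residuals(E, obs, R0, rng)
        assert abs(E[:, 1].mean() - 0.9) < 3 * np.sqrt(0.64 / n)
        assert abs(E[:, 1].var() - 0.64) < 0.01
        assert np.all(E[:, 0] == 1.5)  # observed cells untouched

    def test_fully_missing_individuals_draw_from_r0(self, rng):
        n = 100_000
        E = np.zeros((n, 2))
        obs = np.zeros((n, 2), dtype=bool)
        R0 = np.array([[1.0, -0.5], [-0.5, 2.0]])
        impute_missing_residuals(E, obs, R0, rng)
        np.testing.assert_allclose(np.cov(E.T), R0, atol=0.05)

    def test_no_missing_cells_noop(self, rng):
        E = rng.standard_normal((10, 1))
        before = E.copy()
        impute_missing_residuals(E, np.ones((10, 1), dtype=bool),
                                 np.eye(1), rng)
        np.testing.assert_array_equal(E, before)


class TestGebvAndConfig:
    def test_zero_effects_zero_gebv(self, rng):
        panel = random_panel(rng, 5, 8)
        np.testing.assert_array_equal(compute_gebv(np.zeros((8, 2)), panel),
                                      0.0)

    def test_single_snp_worked_example(self):
        panel = make_panel([[0], [1], [2]])
        gebv = compute_gebv(np.array([[0.5]]), panel)
        np.testing.assert_allclose(gebv[:, 0], [0.0, 0.5, 1.0])

    def test_matches_dense_product(self, rng):
        panel = random_panel(rng, 20, 50)
        eff = rng.standard_normal((50, 2))
        np.testing.assert_allclose(
            compute_gebv(eff, panel),
            panel.dosages.astype(float) @ eff, atol=1e-12)

    def test_snp_set_mismatch_rejected(self, rng):
        panel = random_panel(rng, 5, 8)
        with pytest.raises(ValueError, match="SNPs"):
            compute_gebv(np.zeros((9, 1)), panel)

    def test_stored_sample_bookkeeping(self):
        assert McmcConfig(30_000, 20_000, 10).n_stored == 1000
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, burn_in=100, thin=1)
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, burn_in=10, thin=0)
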