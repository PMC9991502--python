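"""Factor-model state, spike-slab kernel, Gibbs sampler and summaries."""

import numpy as np
import pytest

from megafactor.model_core import (
    Hyperparameters,
    ModelData,
    PosteriorChain,
    fixed_first_factor_spec,
    focal_marker_effects,
    genetic_variance_samples,
    gibbs_sweep,
    initialize_state,
    predict_genetic_values,
    run_mcmc,
    slab_posterior,
    spike_slab_update,
)


def _toy_data(rng, n=30, p=8, t=4, missing=False):
    X = rng.integers(0, 3, size=(n, p)).astype(float)
    Y = rng.normal(size=(n, t))
    if missing:
        Y[rng.random((n, t)) < 0.1] = np.nan
    return ModelData(Y=Y, X2F=X, focal_index=0)


class TestSpikeSlabKernel:
    def test_pi_one_always_excludes(self, rng):
        for _ in range(20):
            b, ind = spike_slab_update(
                rng.normal(size=5), rng.normal(size=5), 1.0, 1.0, 1.0, rng
            )
            assert b == 0.0 and ind == 0

    def test_inclusion_matches_closed_form(self):
        """Empirical inclusion frequency vs the two-component posterior."""
        x = np.array([1.0, 0.0, -1.0])
        y = np.array([0.5, 0.0, -0.5])
        _, _, log_bf = slab_posterior(y, x, 1.0, 1.0)
        p_incl = 1.0 / (1.0 + np.exp(-log_bf))  # pi = 0.5 -> prior odds 1
        rng = np.random.default_rng(99)
        n_rep = 100_000
        hits = sum(
            spike_slab_update(y, x, 1.0, 1.0, 0.5, rng)[1] for _ in range(n_rep)
        )
        se = np.sqrt(p_incl * (1 - p_incl) / n_rep)
        assert abs(hits / n_rep - p_incl) < 3 * se

    def test_pi_zero_posterior_mean_is_ridge(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        s2e, s2b = 0.7, 2.0
        mean, _, _ = slab_posterior(y, x, s2e, s2b)
        ridge = float(x @ y) / (float(x @ x) + s2e / s2b)
        assert mean == pytest.approx(ridge, abs=1e-12)
        # and the sampler centers on it
        draws = [spike_slab_update(y, x, s2e, s2b, 0.0, rng)[0] for _ in range(4000)]
        _, var, _ = slab_posterior(y, x, s2e, s2b)
        assert np.mean(draws) == pytest.approx(ridge, abs=4 * np.sqrt(var / 4000))

    def test_zero_variance_x_prior_odds(self, rng):
        x = np.zeros(6)
        y = rng.normal(size=6)
        draws = [spike_slab_update(y, x, 1.0, 1.0, 0.7, rng) for _ in range(4000)]
        freq = np.mean([d[1] for d in draws])
        assert freq == pytest.approx(0.3, abs=0.03)  # 1 - pi
        assert all(d[0] == 0.0 for d in draws if d[1] == 0)


class TestInitializeState:
    def test_seed_determinism(self, rng):
        data = _toy_data(rng)
        h = Hyperparameters(n_factors=3)
        s1 = initialize_state(data, h, 7)
        s2 = initialize_state(data, h, 7)
        np.testing.assert_array_equal(s1.F, s2.F)
        np.testing.assert_array_equal(s1.Lambda, s2.Lambda)
        np.testing.assert_array_equal(s1.lambda_incl, s2.lambda_incl)

    def test_fixed_first_factor_pinned_forever(self, rng):
        data = _toy_data(rng, t=4)
        h = Hyperparameters(n_factors=2, fixed_loadings=fixed_first_factor_spec(2, 4, 0))
        state = initialize_state(data, h, 0)
        expected = np.array([1.0, 0.0, 0.0, 0.0])
        np.testing.assert_array_equal(state.Lambda[0], expected)
        for _ in range(5):
            gibbs_sweep(state, data, h)
            np.testing.assert_array_equal(state.Lambda[0], expected)

    def test_k_too_large_rejected(self, rng):
        data = _toy_data(rng, n=30, t=4)
        with pytest.raises(ValueError, match="exceeds"):
            initialize_state(data, Hyperparameters(n_factors=5), 0)

    def test_all_missing_column_runs(self, rng):
        data = _toy_data(rng, t=4)
        data.Y[:, 2] = np.nan
        state = initialize_state(data, Hyperparameters(n_factors=2), 0)
        assert np.isfinite(state.Ycur).all()


class TestGibbsSweep:
    def test_sigma2_conditional_centers_on_residual_variance(self, rng):
        """With Lambda pinned to zero the sigma2_R conditional is the
        Inv-Gamma posterior of the column variance of Y - X1 B1."""
        n, t = 10, 2
        Y = rng.normal(0.0, 2.0, size=(n, t))
        data = ModelData(Y=Y, X2F=rng.integers(0, 3, (n, 3)).astype(float))
        mask = np.ones((1, t), dtype=bool)
        h = Hyperparameters(
            n_factors=1, fixed_loadings=(mask, np.zeros((1, t))), a_sigma=1.0, b_sigma=1.0
        )
        state = initialize_state(data, h, 3)
        draws = []
        for _ in range(3000):
            gibbs_sweep(state, data, h)
            draws.append(state.sigma2_R.copy())
        draws = np.array(draws[500:])
        # marginalizing the sampled intercept leaves ss around the column mean
        ss = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
        expected = (1.0 + 0.5 * ss) / (1.0 + 0.5 * (n - 1) - 1.0)  # Inv-Gamma mean
        np.testing.assert_allclose(draws.mean(axis=0), expected, rtol=0.25)

    def test_pi_lambda_one_zeroes_row(self, rng):
        data = _toy_data(rng, t=5)
        h = Hyperparameters(n_factors=3)
        state = initialize_state(data, h, 1)
        state.pi_lambda[:] = np.array([0.5, 1.0, 0.5])
        gibbs_sweep(state, data, h)
        np.testing.assert_array_equal(state.Lambda[1], np.zeros(5))

    def test_trajectory_determinism(self, rng):
        data = _toy_data(rng, missing=True)
        h = Hyperparameters(n_factors=2)
        s1 = initialize_state(data, h, 11)
        s2 = initialize_state(data, h, 11)
        for _ in range(4):
            gibbs_sweep(s1, data, h)
            gibbs_sweep(s2, data, h)
        np.testing.assert_array_equal(s1.B2F, s2.B2F)
        np.testing.assert_array_equal(s1.Ycur, s2.Ycur)

    def test_exclusion_implies_exact_zero_and_finite_log_joint(self, rng):
        data = _toy_data(rng)
        h = Hyperparameters(n_factors=2)
        state = initialize_state(data, h, 5)
        for _ in range(10):
            gibbs_sweep(state, data, h)
            assert np.all(state.B2F[state.b2f_incl == 0] == 0.0)
            free = ~state.fixed_mask
            assert np.all(state.Lambda[(state.lambda_incl == 0) & free] == 0.0)
            assert np.isfinite(state.log_joint)


class TestTauPrior:
    def test_prior_expectation_is_geometric(self):
        """E[tau_k] = (a_delta/b_delta)^(k-1) under the shrinkage prior."""
        rng = np.random.default_rng(0)
        K, reps = 5, 200_000
        delta = np.ones((reps, K))
        delta[:, 1:] = rng.gamma(2.0, 1.0 / 1.0, size=(reps, K - 1))
        tau = np.cumprod(delta, axis=1)
        expected = 2.0 ** np.arange(K)
        np.testing.assert_allclose(tau.mean(axis=0), expected, rtol=0.05)


class TestRunMcmc:
    def test_stored_draw_count(self, rng):
        data = _toy_data(rng, n=20, p=4, t=2)
        h = Hyperparameters(n_factors=2)
        chain = run_mcmc(data, h, n_iter=10_000, burnin=2_000, thin=2, seed=0)
        assert chain.n_draws == 4_000

    def test_invalid_settings(self, rng):
        data = _toy_data(rng)
        h = Hyperparameters(n_factors=2)
        with pytest.raises(ValueError):
            run_mcmc(data, h, n_iter=100, burnin=200, seed=0)
        with pytest.raises(ValueError):
            run_mcmc(data, h, n_iter=100, burnin=10, thin=0, seed=0)
        with pytest.raises(ValueError):
            run_mcmc(data, h, n_iter=100, burnin=10, seed=0, variant="bogus")

    def test_seeded_chain_determinism(self, rng):
        data = _toy_data(rng, missing=True)
        h = Hyperparameters(n_factors=2)
        c1 = run_mcmc(data, h, n_iter=200, burnin=50, thin=3, seed=9)
        c2 = run_mcmc(data, h, n_iter=200, burnin=50, thin=3, seed=9)
        np.testing.assert_array_equal(c1.alpha_sum, c2.alpha_sum)
        np.testing.assert_array_equal(c1.gvar_draws, c2.gvar_draws)

    def test_ridge_decoupling_with_pinned_identity(self, rng):
        """All pi's at 0, K = t, Lambda pinned to identity: each trait is an
        independent ridge regression; posterior-mean fits track the ridge
        oracle."""
        n, p, t = 20, 30, 2
        X = rng.integers(0, 3, (n, p)).astype(float)
        B = rng.normal(0, 0.3, (p, t))
        Y = X @ B + rng.normal(0, 1.0, (n, t))
        mask = np.ones((t, t), dtype=bool)
        h = Hyperparameters(n_factors=t, fixed_loadings=(mask, np.eye(t)))
        data = ModelData(Y=Y, X2F=X)
        chain = run_mcmc(data, h, n_iter=4000, burnin=1000, thin=2, seed=4,
                         variant="megarrblup")
        from megafactor.prediction_cv import gblup_fit, vanraden_grm

        u = predict_genetic_values(chain, X)
        u_ref, _ = gblup_fit(Y[:, 0], vanraden_grm(X))
        r = np.corrcoef(u - u.mean(), u_ref - u_ref.mean())[0, 1]
        assert r > 0.95


class TestChainSummaries:
    def _tiny_chain(self, alpha_draws):
        alpha_draws = np.asarray(alpha_draws, dtype=float)
        return PosteriorChain(
            alpha_sum=alpha_draws.sum(axis=0),
            alpha_sq_sum=(alpha_draws**2).sum(axis=0),
            alpha_draws=alpha_draws.astype(np.float32),
            gvar_draws=np.zeros(len(alpha_draws)),
            Lambda_draws=np.zeros((len(alpha_draws), 1, 1), dtype=np.float32),
            pi_lambda_draws=np.zeros((len(alpha_draws), 1)),
            pi_f_draws=np.zeros((len(alpha_draws), 1)),
            sigma2_R_mean=np.ones(1),
            sigma2_F_mean=np.ones(1),
            sigma2_B2F_mean=np.ones(1),
            log_joint=np.zeros(1),
            n_iter=3,
            burnin=0,
            thin=1,
            seed=0,
            variant="megabayesc",
            focal_index=0,
            n_samples_data=4,
        )

    def test_focal_effects_are_per_draw_averages(self):
        """A 3-draw toy chain: alpha_f equals the hand-averaged per-draw
        products B2F lambda_f."""
        B = [np.array([[1.0], [2.0]]), np.array([[0.0], [1.0]]), np.array([[3.0], [0.0]])]
        lam = [2.0, -1.0, 0.5]
        draws = np.stack([b[:, 0] * l for b, l in zip(B, lam)])
        chain = self._tiny_chain(draws)
        expected = np.mean([b[:, 0] * l for b, l in zip(B, lam)], axis=0)
        np.testing.assert_allclose(focal_marker_effects(chain), expected)

    def test_predict_is_matrix_product(self):
        draws = np.array([[0.5, -1.0], [0.7, -0.8]])
        chain = self._tiny_chain(draws)
        X = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 1.0], [1.0, 1.0]])
        np.testing.assert_allclose(
            predict_genetic_values(chain, X), X @ draws.mean(axis=0)
        )
        with pytest.raises(ValueError, match="markers"):
            predict_genetic_values(chain, np.ones((4, 3)))

    def test_genetic_variance_per_draw(self):
        draws = np.array([[0.5, -1.0], [0.0, 0.0]])
        chain = self._tiny_chain(draws)
        X = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 1.0], [1.0, 1.0]])
        gv = genetic_variance_samples(chain, X)
        np.testing.assert_allclose(gv[0], np.var(X @ draws[0]), rtol=1e-6)
        assert gv[1] == 0.0  # all-zero draw -> constant genetic values


class TestNullCalibration:
    def test_pure_noise_alpha_near_zero(self, rng):
        """With no QTL and Lambda truth zero, posterior-mean alpha_f stays
        within +/- 3 posterior SD of 0 componentwise (small-scale check)."""
        n, p, t = 80, 40, 4
        X = rng.integers(0, 3, (n, p)).astype(float)
        Y = rng.normal(size=(n, t))
        data = ModelData(Y=Y, X2F=X)
        chain = run_mcmc(data, Hyperparameters(n_factors=3), n_iter=1200,
                         burnin=400, thin=2, seed=6)
        from megafactor.model_core import focal_marker_effect_sd

        alpha = focal_marker_effects(chain)
        sd = focal_marker_effect_sd(chain)
        assert np.mean(np.abs(alpha) <= 3 * np.maximum(sd, 1e-12)) >= 0.95
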