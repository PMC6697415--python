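import numpy as np
import pytest
from scipy import integrate, stats
from scipy.stats import multivariate_normal

from msvolt.core import MSVParams, PriorConfig, stationary_moments
from msvolt.mcmc import (MixtureTable, OMORI_TABLE, sample_mixture_indicators,
                         indicator_posterior, kalman_loglik, ffbs_latent,
                         update_mu, update_beta, update_sigma2, run_mcmc,
                         posterior_summary)


def brute_joint_moments(params: MSVParams, T: int):
    """Stacked mean/covariance of the latent VAR(1) with stationary init.

    Independent oracle: Cov(x_t, x_s) = β^{t−s} V₀ for t ≥ s, assembled
    directly from matrix powers (time-major stacking).
    """
    J = params.n_channels
    mu, V0 = stationary_moments(params)
    pows = [np.linalg.matrix_power(params.beta, k) for k in range(T)]
    C = np.zeros((T * J, T * J))
    for t in range(T):
        for s in range(T):
            blk = pows[t - s] @ V0 if t >= s else (pows[s - t] @ V0).T
            C[t * J:(t + 1) * J, s * J:(s + 1) * J] = blk
    return np.tile(mu, T), C


def random_stationary_params(rng, J):
    beta = rng.uniform(-0.5, 0.5, (J, J)) * 0.8 / max(1, J)
    np.fill_diagonal(beta, rng.uniform(0.3, 0.8, J))
    while np.max(np.abs(np.linalg.eigvals(beta))) >= 0.95:
        beta *= 0.8
    return MSVParams(rng.normal(0, 1, J), beta, rng.uniform(0.05, 0.5, J))


class TestMixtureTable:
    def test_matches_log_chi2_moments(self):
        t = OMORI_TABLE
        mean = float(t.weights @ t.means)
        var = float(t.weights @ (t.variances + t.means ** 2) - mean ** 2)
        # E[log χ²₁] = ψ(1/2) + log 2, Var = π²/2
        from scipy.special import digamma
        assert mean == pytest.approx(digamma(0.5) + np.log(2), abs=2e-4)
        assert var == pytest.approx(np.pi ** 2 / 2, abs=2e-3)

    def test_cdf_close_to_exact_law(self):
        # exact CDF of log ε², ε ~ N(0,1): P(log ε² ≤ z) = 2Φ(e^{z/2}) − 1
        t = OMORI_TABLE
        zs = np.linspace(-12, 4, 400)
        exact = 2 * stats.norm.cdf(np.exp(zs / 2)) - 1
        approx = np.sum(t.weights * stats.norm.cdf(
            (zs[:, None] - t.means) / np.sqrt(t.variances)), axis=1)
        assert np.max(np.abs(exact - approx)) < 0.01

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            MixtureTable(weights=[0.5, 0.4], means=[0, 0], variances=[1, 1])


class TestIndicatorSampling:
    def test_single_component_table(self, rng):
        table = MixtureTable(weights=[1.0], means=[-1.27], variances=[4.93])
        ind = sample_mixture_indicators(np.zeros((2, 2, 5)),
                                        np.zeros((2, 2, 5)), table, rng)
        assert np.all(ind == 0)

    def test_site_posterior_sums_to_one(self):
        p = indicator_posterior(0.7, -0.2)
        assert p.sum() == pytest.approx(1.0)

    def test_frequencies_match_analytic_posterior(self, rng):
        z, x = 0.9, -0.4
        p = indicator_posterior(z, x)
        zz = np.full((10 ** 5, 1, 1), z)
        xx = np.full_like(zz, x)
        ind = sample_mixture_indicators(zz, xx, OMORI_TABLE, rng).ravel()
        freq = np.bincount(ind, minlength=10) / ind.size
        assert np.max(np.abs(freq - p)) < 0.01


class TestKalmanLoglik:
    def test_matches_brute_force_joint_gaussian(self, rng):
        """Filter vs dense joint-Gaussian construction, J ≤ 3, T ≤ 6."""
        for _ in range(25):
            J = int(rng.integers(1, 4))
            T = int(rng.integers(2, 7))
            params = random_stationary_params(rng, J)
            ind = rng.integers(0, 10, (1, J, T))
            z = rng.normal(0, 2, (1, J, T))
            m, C = brute_joint_moments(params, T)
            m_obs = OMORI_TABLE.means[ind]
            v_obs = OMORI_TABLE.variances[ind]
            zm = m + m_obs[0].T.ravel()
            zC = C + np.diag(v_obs[0].T.ravel())
            expected = multivariate_normal.logpdf(z[0].T.ravel(), zm, zC)
            assert kalman_loglik(z, ind, params) == pytest.approx(
                expected, abs=1e-8)

    def test_duplicated_event_doubles_total(self, rng):
        params = MSVParams([0.1], [[0.8]], [0.2])
        ind = rng.integers(0, 10, (1, 1, 5))
        z = rng.normal(0, 1, (1, 1, 5))
        one = kalman_loglik(z, ind, params)
        two = kalman_loglik(np.concatenate([z, z]),
                            np.concatenate([ind, ind]), params)
        assert two == pytest.approx(2 * one)

    def test_no_dynamics_factorizes(self, rng):
        # β = 0, tiny Σ: x_t ≈ μ independently, so z factorizes into
        # per-sample univariate Gaussian terms
        params = MSVParams([0.5, -0.5], np.zeros((2, 2)), [1e-12, 1e-12])
        ind = rng.integers(0, 10, (2, 2, 4))
        z = rng.normal(0, 2, (2, 2, 4))
        m_obs = OMORI_TABLE.means[ind]
        sd = np.sqrt(OMORI_TABLE.variances[ind])
        expected = stats.norm.logpdf(
            z, np.array([0.5, -0.5])[None, :, None] + m_obs, sd).sum()
        assert kalman_loglik(z, ind, params) == pytest.approx(expected,
                                                              rel=1e-6)


class TestFFBS:
    def test_zero_state_noise_is_deterministic(self, rng):
        params = MSVParams([0.3], [[0.7]], [0.0])
        ind = rng.integers(0, 10, (1, 1, 6))
        z = rng.normal(0, 1, (1, 1, 6))
        a = ffbs_latent(z, ind, params, np.random.default_rng(1)).x
        b = ffbs_latent(z, ind, params, np.random.default_rng(2)).x
        # V0 = 0 pins x0 = μ and the path follows deterministically
        np.testing.assert_allclose(a, b, atol=1e-10)
        np.testing.assert_allclose(a, 0.3, atol=1e-10)

    def test_moments_match_brute_force_conditional(self, rng):
        """Draw moments vs conditioning the dense joint Gaussian (J=1, T=3)."""
        params = MSVParams([0.2], [[0.7]], [0.3])
        ind = rng.integers(0, 10, (1, 1, 3))
        z = rng.normal(0, 1, (1, 1, 3))
        m, C = brute_joint_moments(params, 3)
        R = np.diag(OMORI_TABLE.variances[ind][0].T.ravel())
        K = C @ np.linalg.inv(C + R)
        resid = z[0].T.ravel() - m - OMORI_TABLE.means[ind][0].T.ravel()
        post_m = m + K @ resid
        post_C = C - K @ C
        draws = np.array([
            ffbs_latent(z, ind, params, np.random.default_rng(i)).x[0, 0]
            for i in range(30000)])
        np.testing.assert_allclose(draws.mean(axis=0), post_m, atol=0.03)
        np.testing.assert_allclose(np.cov(draws.T), post_C, atol=0.03)

    def test_fixed_rng_reproduces_draw(self, rng):
        params = MSVParams([0.2], [[0.7]], [0.3])
        ind = rng.integers(0, 10, (2, 1, 5))
        z = rng.normal(0, 1, (2, 1, 5))
        a = ffbs_latent(z, ind, params, np.random.default_rng(9)).x
        b = ffbs_latent(z, ind, params, np.random.default_rng(9)).x
        np.testing.assert_array_equal(a, b)


class TestParameterUpdates:
    def test_mu_posterior_matches_analytic_conditional(self):
        """Draw moments vs the closed-form normal-normal conditional."""
        cfg = PriorConfig()
        beta = np.array([[0.6]])
        sig2 = np.array([2.0])
        x = np.random.default_rng(0).normal(1.5, 2.0, (1, 1, 3))
        V0 = sig2[0] / (1 - 0.36)
        A = 0.4
        prec = 2 * A ** 2 / sig2[0] + 1 / V0 + 1 / cfg.mu_prior_var
        b = (A * (x[0, 0, 1:] - 0.6 * x[0, 0, :-1]).sum() / sig2[0]
             + x[0, 0, 0] / V0)
        draws = np.array([update_mu(x, beta, sig2, cfg,
                                    np.random.default_rng(i))[0]
                          for i in range(20000)])
        assert draws.mean() == pytest.approx(b / prec, abs=0.05)
        assert draws.var() == pytest.approx(1 / prec, rel=0.05)

    def test_mu_flat_prior_tracks_sample_mean(self, rng):
        cfg = PriorConfig(mu_prior_var=1e6)
        x = rng.normal(2.0, 1.0, (1, 1, 5000))
        draws = np.array([update_mu(x, np.zeros((1, 1)), np.ones(1), cfg,
                                    np.random.default_rng(i))[0]
                          for i in range(200)])
        assert draws.mean() == pytest.approx(x.mean(), abs=0.05)

    def test_beta_self_proposal_always_accepted(self, rng):
        x = rng.normal(0, 1, (1, 2, 50))
        beta = 0.5 * np.eye(2)
        _, acc = update_beta(beta, x, np.zeros(2), np.ones(2), PriorConfig(),
                             rng, step=0.0, proposal="rw")
        assert acc.all()

    def test_beta_draws_stay_stationary(self, rng):
        from msvolt.core import stationarity_check
        x = rng.normal(0, 1, (2, 2, 100))
        beta = 0.5 * np.eye(2)
        for prop in ("independence", "rw"):
            b = beta.copy()
            for _ in range(50):
                b, _ = update_beta(b, x, np.zeros(2), np.ones(2),
                                   PriorConfig(), rng, step=0.3,
                                   proposal=prop)
                assert stationarity_check(b)

    def test_beta_recovery_from_latent_paths(self, rng):
        """Repeated updates on x from a known VAR(1) concentrate near truth."""
        true_beta = np.array([[0.7, 0.1], [-0.15, 0.6]])
        sig2 = np.array([0.1, 0.1])
        T = 10 ** 5
        x = np.zeros((1, 2, T))
        eps = rng.standard_normal((T, 2)) * np.sqrt(sig2)
        for t in range(1, T):
            x[0, :, t] = true_beta @ x[0, :, t - 1] + eps[t]
        beta = 0.5 * np.eye(2)
        draws = []
        for i in range(60):
            beta, _ = update_beta(beta, x, np.zeros(2), sig2, PriorConfig(),
                                  rng)
            if i >= 10:
                draws.append(beta)
        est = np.mean(draws, axis=0)
        np.testing.assert_allclose(est, true_beta, atol=0.02)

    def test_sigma2_positive_and_collapses_without_innovations(self, rng):
        x = np.full((1, 1, 10 ** 4), 0.7)  # constant path: zero innovations
        s = np.array([1.0])
        for _ in range(20):
            s, _ = update_sigma2(s, x, np.array([0.7]), np.array([[0.5]]),
                                 PriorConfig(), rng)
            assert s[0] > 0
        assert s[0] < 0.01

    def test_sigma2_recovery(self, rng):
        true = 0.1
        T = 10 ** 5
        x = np.zeros((1, 1, T))
        eps = rng.standard_normal(T) * np.sqrt(true)
        for t in range(1, T):
            x[0, 0, t] = 0.8 * x[0, 0, t - 1] + eps[t]
        s = np.array([1.0])
        draws = []
        for i in range(60):
            s, _ = update_sigma2(s, x, np.zeros(1), np.array([[0.8]]),
                                 PriorConfig(), rng)
            if i >= 10:
                draws.append(s[0])
        assert np.mean(draws) == pytest.approx(true, rel=0.2)


class TestRunMCMC:
    def test_same_seed_identical_chains(self, small_msv_data):
        data, _ = small_msv_data
        a = run_mcmc(data, n_iter=20, burn_in=5, seed=7, latent_thin=5)
        b = run_mcmc(data, n_iter=20, burn_in=5, seed=7, latent_thin=5)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.latent_draws, b.latent_draws)

    def test_chain_bookkeeping(self, small_msv_data):
        data, _ = small_msv_data
        d = run_mcmc(data, n_iter=30, burn_in=10, seed=0, latent_thin=4)
        assert d.n_draws == 20
        assert d.latent_draws.shape[0] == 5
        assert np.all(np.isfinite(d.loglik))

    def test_diagonal_constraint_matches_univariate_fits(self):
        """A diagonal-constrained J=2 fit equals two independent SV fits."""
        from msvolt.synthetic import SimulationSpec, simulate_msv
        p = MSVParams([0.0, 0.4], np.diag([0.8, 0.7]), [0.1, 0.1])
        spec = SimulationSpec(n_channels=2, n_events=40,
                              samples_per_event=200, params=p, seed=2)
        data, _ = simulate_msv(spec)
        joint = run_mcmc(data, n_iter=150, burn_in=50, seed=3, diagonal=True,
                         latent_thin=0)
        est_joint, _ = posterior_summary(joint)
        assert np.all(est_joint.beta[~np.eye(2, dtype=bool)] == 0)
        for j in range(2):
            single = run_mcmc(data.data[:, j:j + 1, :], n_iter=150,
                              burn_in=50, seed=10 + j, latent_thin=0)
            est_j, _ = posterior_summary(single)
            assert est_j.beta[0, 0] == pytest.approx(est_joint.beta[j, j],
                                                     abs=0.05)
            assert est_j.mu[0] == pytest.approx(est_joint.mu[j], abs=0.1)

    def test_rw_acceptance_rate_in_tuning_band(self, small_msv_data):
        """Adapted random-walk acceptance lands in (0.1, 0.7)."""
        data, _ = small_msv_data
        d = run_mcmc(data, n_iter=250, burn_in=150, seed=1, latent_thin=0,
                     proposal="rw")
        assert 0.1 < d.accept_beta < 0.7
        assert 0.1 < d.accept_sigma2 < 0.7


class TestPosteriorSummary:
    def test_constant_chain_returns_constant(self):
        from msvolt.mcmc import PosteriorDraws
        mu = np.tile([1.0, 2.0], (5, 1))
        beta = np.tile(0.5 * np.eye(2), (5, 1, 1))
        sig = np.tile([0.1, 0.2], (5, 1))
        d = PosteriorDraws(mu=mu, beta=beta, sigma2=sig, loglik=np.zeros(5))
        params, latents = posterior_summary(d)
        np.testing.assert_array_equal(params.mu, [1.0, 2.0])
        assert latents is None

    def test_nonstationary_mean_beta_warns(self):
        from msvolt.mcmc import PosteriorDraws
        b1 = np.array([[0.9, 0.8], [0.0, 0.9]])
        b2 = np.array([[0.9, 0.0], [0.8, 0.9]])
        d = PosteriorDraws(mu=np.zeros((2, 2)),
                           beta=np.stack([b1, b2]),
                           sigma2=np.full((2, 2), 0.1),
                           loglik=np.zeros(2))
        with pytest.warns(RuntimeWarning, match="not stationary"):
            posterior_summary(d)

    def test_empty_chain_rejected(self):
        from msvolt.mcmc import PosteriorDraws
        d = PosteriorDraws(mu=np.zeros((0, 1)), beta=np.zeros((0, 1, 1)),
                           sigma2=np.zeros((0, 1)), loglik=np.zeros(0))
        with pytest.raises(ValueError):
            posterior_summary(d)
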