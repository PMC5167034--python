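"""Prior construction, sampler correctness and posterior summaries."""

import math

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import lognorm

from estabkit import (
    InferenceParams,
    Scenario,
    build_priors,
    log_posterior,
    loglikelihood,
    mh_sample,
    posterior_summary,
    species_params_from_delta,
)
from estabkit.mcmc import (
    _loglik_nb,
    effective_sample_size,
    random_walk_metropolis,
)
from estabkit.likelihood import SIMPSON_NODES, VARIANCE_FLOOR
from estabkit.metrics import simulate_observation_series


def _anchors(delta, alpha=1.0):
    sp = species_params_from_delta(delta)
    return InferenceParams.from_truth(sp, resident_K=10_000.0, alpha=alpha)


class TestPriors:
    @pytest.mark.parametrize(
        "scenario,free",
        [
            (Scenario.ALL_FIXED, (False, False, False)),
            (Scenario.PRIOR_K, (False, True, False)),
            (Scenario.PRIOR_K_N, (False, True, True)),
            (Scenario.PRIOR_K_N_R, (True, True, True)),
        ],
    )
    def test_free_parameters_per_scenario(self, scenario, free):
        priors = build_priors(scenario, 0.3, _anchors(1.0))
        assert priors.free == free
        assert priors.n_free == 1 + sum(free)  # alpha always free

    def test_narrow_prior_concentrates_on_anchor(self):
        """sigma = 0.01: the lognormal 99% interval spans < 6% around K."""
        priors = build_priors(Scenario.PRIOR_K, 0.01, _anchors(1.0))
        dist = lognorm(s=priors.sigma, scale=priors.anchors.K)
        lo, hi = dist.ppf([0.005, 0.995])
        assert hi / lo - 1.0 < 0.06
        assert dist.median() == pytest.approx(priors.anchors.K)

    def test_unknown_scenario_and_bad_sigma(self):
        with pytest.raises(ValueError, match="scenario"):
            build_priors("everything_free", 0.3, _anchors(1.0))
        with pytest.raises(ValueError, match="sigma"):
            build_priors(Scenario.PRIOR_K, 5.0, _anchors(1.0))


class TestLogPosterior:
    def test_flat_prior_region_differences_equal_likelihood(self, toy_obs):
        priors = build_priors(Scenario.ALL_FIXED, 0.3, _anchors(1.0))
        latent = [50.0, 62.0, 80.0]
        t1 = _anchors(1.0, alpha=0.5)
        t2 = _anchors(1.0, alpha=0.7)
        d_post = log_posterior(t1, latent, toy_obs, priors) - log_posterior(
            t2, latent, toy_obs, priors
        )
        d_lik = loglikelihood(toy_obs, latent, t1) - loglikelihood(toy_obs, latent, t2)
        assert d_post == pytest.approx(d_lik, rel=1e-12)

    def test_out_of_support_alpha(self, toy_obs):
        priors = build_priors(Scenario.ALL_FIXED, 0.3, _anchors(1.0))
        assert log_posterior(_anchors(1.0, 2.5), [50, 62, 80], toy_obs, priors) == -math.inf

    def test_hand_assembled_with_lognormal_prior(self, toy_obs):
        """Likelihood plus the lognormal log-density on K, assembled by hand."""
        anchors = _anchors(1.0, alpha=0.5)
        priors = build_priors(Scenario.PRIOR_K, 0.3, anchors)
        theta = InferenceParams(
            anchors.log_r, math.log(9_000.0), anchors.log_N, anchors.log_K_R, 0.5
        )
        latent = [50.0, 62.0, 80.0]
        expected = loglikelihood(toy_obs, latent, theta) + lognorm.logpdf(
            9_000.0, s=0.3, scale=anchors.K
        )
        assert log_posterior(theta, latent, toy_obs, priors) == pytest.approx(
            expected, rel=1e-10
        )


class TestKernelConsistency:
    def test_jitted_loglik_matches_reference(self, theta_d1_a05):
        """The numba likelihood used inside the sampler agrees with the
        reference implementation at random admissible states."""
        obs = simulate_observation_series(0.5, 1.0, seed=3)
        rng = np.random.default_rng(0)
        dts = np.diff(np.concatenate(([0.0], obs.times)))
        counts = obs.counts.astype(float)
        lgam = gammaln(counts + 1.0)
        for _ in range(5):
            latent = np.maximum(obs.counts / obs.f, 1.0) * rng.lognormal(
                0, 0.2, obs.d
            )
            alpha = rng.uniform(0.2, 1.5)
            th = InferenceParams(
                theta_d1_a05.log_r,
                theta_d1_a05.log_K,
                theta_d1_a05.log_N,
                theta_d1_a05.log_K_R,
                alpha,
            )
            y = np.array([alpha, th.log_r, th.log_K, th.log_N])
            fast = _loglik_nb(
                dts, counts, lgam, math.log(obs.f), obs.f, float(obs.n0),
                y, np.log(latent), th.log_K_R, SIMPSON_NODES, VARIANCE_FLOOR,
            )
            assert fast == pytest.approx(loglikelihood(obs, latent, th), rel=1e-9)


class TestSampler:
    def test_conjugate_toy_recovery(self):
        """Known-variance Gaussian mean with Gaussian prior: the generic
        random-walk sampler recovers the closed-form posterior within 2%."""
        data = np.array([1.2, 0.4, 0.8, 1.5, 0.9, 1.1, 0.3, 0.7])
        s2, mu0, tau2 = 0.5, 0.0, 4.0
        n = len(data)
        post_var = 1.0 / (n / s2 + 1.0 / tau2)
        post_mean = post_var * (data.sum() / s2 + mu0 / tau2)

        def logpost(x):
            m = x[0]
            return -0.5 * np.sum((data - m) ** 2) / s2 - 0.5 * (m - mu0) ** 2 / tau2

        draws = random_walk_metropolis(logpost, [0.0], [0.6], 100_000, seed=4, burn=2_000)
        assert draws[:, 0].mean() == pytest.approx(post_mean, abs=0.02 * abs(post_mean))
        assert draws[:, 0].std() == pytest.approx(math.sqrt(post_var), rel=0.02)

    def test_identical_seed_identical_chain(self):
        obs = simulate_observation_series(0.8, 1.75, seed=9)
        priors = build_priors(Scenario.PRIOR_K, 0.3, _anchors(1.75))
        a = mh_sample(obs, priors, n_iter=3_000, n_burn=1_000, thin=2, seed=7)
        b = mh_sample(obs, priors, n_iter=3_000, n_burn=1_000, thin=2, seed=7)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.latent, b.latent)
        c = mh_sample(obs, priors, n_iter=3_000, n_burn=1_000, thin=2, seed=8)
        assert not np.array_equal(a.alpha, c.alpha)

    def test_establishment_signal_recovered(self):
        """Data generated at alpha = 0.5 put most posterior mass below 1."""
        obs = simulate_observation_series(0.5, 1.0, seed=2)
        priors = build_priors(Scenario.ALL_FIXED, 0.3, _anchors(1.0))
        sample = mh_sample(obs, priors, n_iter=10_000, n_burn=4_000, seed=1)
        s = posterior_summary(sample)
        assert s["mass_below_1"] > 0.5

    def test_chain_health_at_default_settings(self):
        """Post-burn-in acceptance within [0.1, 0.6]; ESS(alpha) >= 200."""
        obs = simulate_observation_series(0.8, 1.75, seed=21)
        priors = build_priors(Scenario.PRIOR_K_N_R, 0.3, _anchors(1.75))
        sample = mh_sample(obs, priors, seed=3)
        for name in ("alpha", "r", "K", "N", "latent"):
            assert 0.1 <= sample.acceptance[name] <= 0.6, name
        assert posterior_summary(sample)["ess_alpha"] >= 200

    def test_from_origin_mode_is_distinct_and_reproducible(self):
        obs = simulate_observation_series(0.8, 1.75, seed=9)
        priors = build_priors(Scenario.ALL_FIXED, 0.3, _anchors(1.75))
        a = mh_sample(obs, priors, n_iter=3_000, n_burn=1_000, seed=7, mode="from-origin")
        b = mh_sample(obs, priors, n_iter=3_000, n_burn=1_000, seed=7, mode="from-origin")
        assert np.array_equal(a.alpha, b.alpha)
        markov = mh_sample(obs, priors, n_iter=3_000, n_burn=1_000, seed=7)
        assert not np.array_equal(a.alpha, markov.alpha)
        with pytest.raises(ValueError, match="mode"):
            mh_sample(obs, priors, n_iter=3_000, n_burn=1_000, seed=7, mode="exact")

    def test_draw_count_contract(self):
        obs = simulate_observation_series(0.8, 1.75, seed=9)
        priors = build_priors(Scenario.ALL_FIXED, 0.3, _anchors(1.75))
        sample = mh_sample(obs, priors, n_iter=5_000, n_burn=2_000, thin=3, seed=0)
        assert sample.n_draws == (5_000 - 2_000 + 2) // 3
        assert np.all((sample.alpha >= 0) & (sample.alpha <= 2))

    def test_bad_chain_settings_rejected(self):
        obs = simulate_observation_series(0.8, 1.75, seed=9)
        priors = build_priors(Scenario.ALL_FIXED, 0.3, _anchors(1.75))
        with pytest.raises(ValueError):
            mh_sample(obs, priors, n_iter=100, n_burn=200, seed=0)


class TestPosteriorSummary:
    def _fake_sample(self, alpha):
        from estabkit.mcmc import PosteriorSample

        n = len(alpha)
        return PosteriorSample(
            alpha=np.asarray(alpha, dtype=float),
            r=np.ones(n), K=np.ones(n), N=np.ones(n),
            latent=np.ones((n, 1)),
            acceptance={}, n_iter=0, n_burn=0, thin=1, seed=0,
            scenario=Scenario.ALL_FIXED, sigma=0.3,
        )

    def test_tail_masses(self):
        s = posterior_summary(self._fake_sample([0.2, 0.4, 0.6, 0.8]))
        assert s["mass_below_1"] == 1.0 and s["mass_above_1"] == 0.0
        s = posterior_summary(self._fake_sample([0.5, 0.5, 1.5, 1.5]))
        assert s["mass_above_1"] == 0.5

    def test_degenerate_sample_zero_se(self):
        s = posterior_summary(self._fake_sample([0.7] * 10))
        assert s["se_alpha"] == 0.0
        assert s["mean_alpha"] == pytest.approx(0.7)


def test_effective_sample_size_iid_vs_correlated():
    rng = np.random.default_rng(0)
    iid = rng.normal(size=4_000)
    assert effective_sample_size(iid) > 2_000
    ar = np.empty(4_000)
    ar[0] = 0.0
    for i in range(1, 4_000):
        ar[i] = 0.95 * ar[i - 1] + rng.normal()
    assert effective_sample_size(ar) < 1_000
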