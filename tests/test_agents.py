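"""Choice models: GP posterior, mean tracker, UCB valuation and policies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from devtraject import agents, envgen
from devtraject.agents import (GP_UCB, BETA_LESION, LAMBDA_LESION, TAU_LESION,
                               ModelConfig, Observations, ParameterSet,
                               Posterior, bmt_update, epsilon_greedy_policy,
                               gp_posterior, model_predict, softmax_policy,
                               ucb_values)


def brute_force_gp(tiles, rewards, lam, noise_var):
    """Independent per-option oracle: direct evaluation of the GP conditionals."""
    K = envgen.kernel_matrix(lam)
    Kxx = K[np.ix_(tiles, tiles)] + noise_var * np.eye(len(tiles))
    inv = np.linalg.inv(Kxx)
    y = np.asarray(rewards, dtype=float)
    mean = np.empty(64)
    var = np.empty(64)
    for opt in range(64):
        k_star = K[tiles, opt]
        mean[opt] = k_star @ inv @ y
        var[opt] = K[opt, opt] - k_star @ inv @ k_star
    return mean, var


class TestGPPosterior:
    def test_empty_history_is_prior(self):
        post = gp_posterior(Observations([], []), lambda_=1.0)
        assert np.allclose(post.mean, 0.0)
        assert np.allclose(post.var, 1.0)

    def test_single_observation_scalar_form(self):
        # one observation y=1 at x0 shrinks the mean by 1 / (1 + noise)
        post = gp_posterior(Observations([10], [1.0]), lambda_=2.0,
                            noise_var=4e-4)
        assert post.mean[10] == pytest.approx(1.0 / (1.0 + 4e-4), rel=1e-12)

    def test_matches_brute_force_oracle(self):
        tiles = [0, 9, 27, 9, 55]
        rewards = [0.3, 0.5, -0.2, 0.55, 0.9]
        post = gp_posterior(Observations(tiles, rewards), lambda_=1.3,
                            noise_var=4e-4)
        mean, var = brute_force_gp(tiles, rewards, 1.3, 4e-4)
        assert np.allclose(post.mean, mean, atol=1e-8)
        assert np.allclose(post.var, var, atol=1e-8)

    def test_no_generalization_with_tiny_lengthscale(self):
        post = gp_posterior(Observations([0], [0.8]), lambda_=0.5)
        far = envgen.tile_index(7, 7)
        assert post.mean[far] == pytest.approx(0.0, abs=1e-6)
        assert post.var[far] == pytest.approx(1.0, abs=1e-6)

    def test_variance_shrinks_at_observed_location(self):
        post = gp_posterior(Observations([20], [0.4]), lambda_=1.0)
        assert post.var[20] < 1.0
        assert np.all(post.var <= 1.0 + 1e-12)

    def test_interpolation_as_noise_vanishes(self):
        post = gp_posterior(Observations([5], [0.7]), lambda_=1.0,
                            noise_var=1e-10)
        assert post.mean[5] == pytest.approx(0.7, abs=1e-6)

    @given(st.integers(min_value=0, max_value=63),
           st.floats(min_value=-1, max_value=1))
    @settings(max_examples=20, deadline=None)
    def test_posterior_variance_never_exceeds_prior(self, tile, reward):
        post = gp_posterior(Observations([tile], [reward]), lambda_=2.0)
        assert np.all(post.var <= 1.0 + 1e-12)


class TestBMT:
    def test_direct_update_evaluation(self):
        post = Posterior(mean=np.full(64, 0.5), var=np.full(64, 5.0))
        new = bmt_update(post, choice=3, reward=1.0, theta_err_sq=1.0)
        gain = 5.0 / 6.0
        assert new.mean[3] == pytest.approx(0.5 + gain * 0.5)
        assert new.var[3] == pytest.approx(5.0 * (1 - gain))

    def test_unchosen_options_unchanged(self):
        post = Posterior(mean=np.full(64, 0.5), var=np.full(64, 5.0))
        new = bmt_update(post, choice=3, reward=1.0, theta_err_sq=1.0)
        mask = np.arange(64) != 3
        assert np.array_equal(new.mean[mask], post.mean[mask])
        assert np.array_equal(new.var[mask], post.var[mask])

    def test_gain_half_when_variance_equals_error(self):
        post = Posterior(mean=np.zeros(64), var=np.full(64, 0.7))
        new = bmt_update(post, choice=0, reward=1.0, theta_err_sq=0.7)
        assert new.mean[0] == pytest.approx(0.5)

    def test_matches_conjugate_normal_closed_form(self):
        """Repeated observations of one option reduce to the known-variance
        normal-normal posterior."""
        m0, v0, theta = 0.5, 5.0, 0.25
        rewards = [0.8, 0.6, 0.9, 0.7]
        post = agents.bmt_posterior(
            Observations([12] * len(rewards), rewards), theta,
            prior_mean=m0, prior_var=v0)
        n = len(rewards)
        post_var = 1.0 / (1.0 / v0 + n / theta)
        post_mean = post_var * (m0 / v0 + np.sum(rewards) / theta)
        assert post.mean[12] == pytest.approx(post_mean, rel=1e-10)
        assert post.var[12] == pytest.approx(post_var, rel=1e-10)

    def test_invalid_error_variance(self):
        post = Posterior(mean=np.zeros(64), var=np.ones(64))
        with pytest.raises(ValueError):
            bmt_update(post, 0, 1.0, theta_err_sq=0.0)


class TestUCB:
    def test_beta_zero_returns_mean(self):
        post = Posterior(mean=np.linspace(0, 1, 64), var=np.ones(64))
        assert np.array_equal(ucb_values(post, 0.0), post.mean)

    def test_bonus_added(self):
        post = Posterior(mean=np.zeros(64), var=np.ones(64))
        assert np.allclose(ucb_values(post, 0.5), 0.5)

    def test_monotone_in_beta(self):
        post = Posterior(mean=np.zeros(64), var=np.full(64, 0.5))
        assert np.all(ucb_values(post, 1.0) > ucb_values(post, 0.5))


class TestPolicies:
    def test_softmax_uniform_for_equal_values(self):
        p = softmax_policy(np.zeros(64), tau=0.1)
        assert np.allclose(p, 1 / 64)

    def test_softmax_two_option_logistic(self):
        p = softmax_policy(np.array([0.0, 1.0]), tau=1.0)
        assert p[1] == pytest.approx(0.7311, abs=1e-4)
        assert p[0] == pytest.approx(0.2689, abs=1e-4)

    def test_softmax_high_temperature_uniform(self):
        p = softmax_policy(np.linspace(0, 1, 64), tau=1e6)
        assert np.allclose(p, 1 / 64, atol=1e-6)

    def test_softmax_rejects_bad_temperature(self):
        with pytest.raises(ValueError):
            softmax_policy(np.zeros(4), tau=0.0)

    def test_epsilon_one_uniform(self):
        p = epsilon_greedy_policy(np.linspace(0, 1, 64), epsilon=1.0)
        assert np.allclose(p, 1 / 64)

    def test_epsilon_half_unique_max(self):
        values = np.zeros(64)
        values[17] = 1.0
        p = epsilon_greedy_policy(values, epsilon=0.5)
        assert p[17] == pytest.approx(0.5 + 0.5 / 64)

    def test_epsilon_zero_tie_split(self):
        values = np.zeros(64)
        values[[3, 40]] = 2.0
        p = epsilon_greedy_policy(values, epsilon=0.0)
        assert p[3] == pytest.approx(0.5)
        assert p[40] == pytest.approx(0.5)

    @given(st.floats(min_value=0, max_value=1),
           st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_policies_are_distributions(self, epsilon, seed):
        values = np.random.default_rng(seed).normal(size=64)
        for p in (softmax_policy(values, tau=0.2),
                  epsilon_greedy_policy(values, epsilon)):
            assert np.all(p >= 0)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)


class TestModelPredict:
    def _history(self):
        return Observations([5, 20, 60], [0.3, 0.6, 0.2])

    def test_gp_ucb_matches_componentwise_oracle(self):
        params = ParameterSet(lambda_=1.1, beta=0.4, tau=0.07)
        probs = model_predict(ModelConfig(GP_UCB), params, self._history())
        mean, var = brute_force_gp([5, 20, 60], [0.3, 0.6, 0.2], 1.1,
                                   agents.DEFAULT_OBS_NOISE_VAR)
        q = mean + 0.4 * np.sqrt(np.maximum(var, 0))
        expected = np.exp(q / 0.07 - max(q / 0.07))
        expected /= expected.sum()
        assert np.allclose(probs, expected, atol=1e-8)

    def test_beta_lesion_equals_gp_ucb_at_beta_zero(self):
        obs = self._history()
        lesion = model_predict(ModelConfig(BETA_LESION),
                               ParameterSet(lambda_=1.0, tau=0.1), obs)
        # same valuation path through the full model with an explicit tiny beta
        full = model_predict(ModelConfig(GP_UCB),
                             ParameterSet(lambda_=1.0, beta=1e-300, tau=0.1),
                             obs)
        assert np.allclose(lesion, full, atol=1e-12)

    def test_huge_temperature_is_uniform(self):
        probs = model_predict(ModelConfig(GP_UCB),
                              ParameterSet(lambda_=1.0, beta=0.5, tau=1e9),
                              self._history())
        assert np.allclose(probs, 1 / 64, atol=1e-8)

    def test_lambda_lesion_uses_mean_tracker(self):
        params = ParameterSet(theta_err_sq=0.5, beta=0.2, tau=0.05)
        probs = model_predict(ModelConfig(LAMBDA_LESION), params,
                              self._history())
        assert probs.sum() == pytest.approx(1.0)

    def test_parameter_model_mismatch_raises(self):
        with pytest.raises(agents.ConfigurationError):
            model_predict(ModelConfig(GP_UCB),
                          ParameterSet(lambda_=1.0, beta=0.3), self._history())
        with pytest.raises(agents.ConfigurationError):
            model_predict(ModelConfig(TAU_LESION),
                          ParameterSet(lambda_=1.0, beta=0.3, tau=0.1),
                          self._history())

    def test_sequential_probs_match_from_scratch_prediction(self):
        rng = np.random.default_rng(0)
        tiles = rng.integers(0, 64, size=8)
        rewards = rng.uniform(0.1, 0.9, size=8)
        params = ParameterSet(lambda_=0.9, beta=0.3, tau=0.05)
        cfg = ModelConfig(GP_UCB)
        seq = agents.predict_round_probs(cfg, params, tiles, rewards)
        for t in range(len(tiles) - 1):
            scratch = model_predict(
                cfg, params, Observations(tiles[:t + 1], rewards[:t + 1]))
            assert np.allclose(seq[t], scratch, atol=1e-9)
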