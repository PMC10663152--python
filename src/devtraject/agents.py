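"""Probabilistic choice models over the 64 grid options.

The full model (GP-UCB) combines three components:

1. *Learning*: Gaussian-process regression with an RBF kernel generalizes
   reward observations across the grid, yielding a posterior mean m(x) and
   variance v(x) per option.
2. *Valuation*: upper-confidence-bound sampling, q(x) = m(x) + beta * sqrt(v(x)),
   where beta weights uncertainty-directed exploration.
3. *Choice*: a softmax policy, p(x) proportional to exp(q(x) / tau), where the
   temperature tau controls undirected (random) exploration.

Three lesions remove one component each: the generalization lesion replaces
the GP with a Bayesian mean tracker (an option-independent Kalman filter with
error variance theta_err_sq); the exploration-bonus lesion fixes beta = 0;
the temperature lesion swaps the softmax for an epsilon-greedy policy.

Rewards enter the models on a normalized scale: raw task rewards (5..45) are
divided by :data:`MODEL_REWARD_SCALE` (50), so the zero-mean GP prior acts as
a mildly pessimistic prior.  The GP observation-noise variance defaults to
the generative N(0, 1) noise on that scale, (1/50)^2, and is not a free
parameter, so every full model has exactly three free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .envgen import N_OPTIONS, SQDIST, kernel_matrix

#: Raw task rewards are divided by this before entering any model.
MODEL_REWARD_SCALE = 50.0

#: GP observation-noise variance on the normalized scale: (1 / 50)^2.
DEFAULT_OBS_NOISE_VAR = (1.0 / MODEL_REWARD_SCALE) ** 2

#: Bayesian mean tracker prior (normalized scale).
DEFAULT_BMT_PRIOR_MEAN = 0.5
DEFAULT_BMT_PRIOR_VAR = 5.0

GP_UCB = "GP-UCB"
LAMBDA_LESION = "lambda-lesion"
BETA_LESION = "beta-lesion"
TAU_LESION = "tau-lesion"
MODEL_IDS = (GP_UCB, LAMBDA_LESION, BETA_LESION, TAU_LESION)

#: Free parameters of each model, in the order used by the fitting module.
FREE_PARAMS = {
    GP_UCB: ("lambda_", "beta", "tau"),
    LAMBDA_LESION: ("theta_err_sq", "beta", "tau"),
    BETA_LESION: ("lambda_", "tau"),
    TAU_LESION: ("lambda_", "beta", "epsilon"),
}


class ConfigurationError(ValueError):
    """Model id and parameter set do not match."""


@dataclass
class Observations:
    """A round's observation history: chosen tiles and normalized rewards.

    ``tiles`` are flat indices (row-major); the round's initial random reveal
    is the first entry.  Repeat choices are allowed.
    """

    tiles: np.ndarray
    rewards: np.ndarray

    def __post_init__(self) -> None:
        self.tiles = np.asarray(self.tiles, dtype=int).ravel()
        self.rewards = np.asarray(self.rewards, dtype=float).ravel()
        if self.tiles.size != self.rewards.size:
            raise ValueError("tiles and rewards must have equal length")
        if self.tiles.size and not (
            self.tiles.min() >= 0 and self.tiles.max() < N_OPTIONS
        ):
            raise ValueError("tile indices off the lattice")

    def __len__(self) -> int:
        return self.tiles.size


@dataclass
class Posterior:
    """Per-option posterior mean and variance (normalized reward units)."""

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.mean.shape != (N_OPTIONS,) or self.var.shape != (N_OPTIONS,):
            raise ValueError(f"posterior needs {N_OPTIONS} entries per field")
        if np.any(self.var < -1e-12):
            raise ValueError("negative posterior variance")
        self.var = np.maximum(self.var, 0.0)


@dataclass(frozen=True)
class ParameterSet:
    """A point in strategy space; each model uses its own subset of fields."""

    lambda_: float | None = None
    beta: float | None = None
    tau: float | None = None
    epsilon: float | None = None
    theta_err_sq: float | None = None

    def __post_init__(self) -> None:
        for name in ("lambda_", "beta", "tau", "theta_err_sq"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.epsilon is not None and not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")

    def require(self, model_id: str) -> None:
        """Raise ConfigurationError unless this set covers the model's free params."""
        if model_id not in FREE_PARAMS:
            raise ConfigurationError(f"unknown model id {model_id!r}")
        missing = [p for p in FREE_PARAMS[model_id] if getattr(self, p) is None]
        if missing:
            raise ConfigurationError(
                f"model {model_id!r} needs parameters {missing}, not provided"
            )

    def as_array(self, model_id: str) -> np.ndarray:
        return np.array([getattr(self, p) for p in FREE_PARAMS[model_id]], dtype=float)

    @classmethod
    def from_array(cls, model_id: str, values: Sequence[float]) -> "ParameterSet":
        names = FREE_PARAMS[model_id]
        if len(values) != len(names):
            raise ConfigurationError(
                f"model {model_id!r} expects {len(names)} parameters, got {len(values)}"
            )
        return cls(**dict(zip(names, map(float, values))))


@dataclass(frozen=True)
class ModelConfig:
    """Fixed (non-fitted) model settings."""

    model_id: str = GP_UCB
    obs_noise_var: float = DEFAULT_OBS_NOISE_VAR
    bmt_prior_mean: float = DEFAULT_BMT_PRIOR_MEAN
    bmt_prior_var: float = DEFAULT_BMT_PRIOR_VAR

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ConfigurationError(f"unknown model id {self.model_id!r}")
        if not self.obs_noise_var > 0:
            raise ValueError("obs_noise_var must be positive")
        if not self.bmt_prior_var > 0:
            raise ValueError("bmt_prior_var must be positive")


def normalize_rewards(raw) -> np.ndarray:
    """Map raw task rewards onto the modelling scale (divide by 50)."""
    return np.asarray(raw, dtype=float) / MODEL_REWARD_SCALE


# ---------------------------------------------------------------------------
# Learners
# ---------------------------------------------------------------------------


class SequentialGP:
    """GP posterior over the grid, updated one observation at a time.

    Maintains the Cholesky solves incrementally so that appending the t-th
    observation costs O(t * 64) instead of refactorizing: with
    A = L^-1 K(X, grid) and w = L^-1 y (L the Cholesky factor of
    K(X, X) + noise * I), the posterior is m = A' w and v = 1 - sum(A^2).
    """

    def __init__(self, lambda_: float, noise_var: float = DEFAULT_OBS_NOISE_VAR,
                 kernel: np.ndarray | None = None, max_obs: int = 32):
        if not lambda_ > 0:
            raise ValueError(f"lambda_ must be positive, got {lambda_}")
        if not noise_var > 0:
            raise ValueError(f"noise_var must be positive, got {noise_var}")
        self.kernel = kernel_matrix(lambda_) if kernel is None else kernel
        self.noise_var = noise_var
        self._A = np.empty((max_obs, N_OPTIONS))
        self._w = np.empty(max_obs)
        self._t = 0
        self._mean = np.zeros(N_OPTIONS)
        self._sumsq = np.zeros(N_OPTIONS)

    def update(self, tile: int, reward: float) -> None:
        t = self._t
        if t >= self._w.size:  # grow lazily; rounds rarely exceed max_obs
            self._A = np.concatenate([self._A, np.empty_like(self._A)])
            self._w = np.concatenate([self._w, np.empty_like(self._w)])
        k_row = self.kernel[tile]
        if t == 0:
            ell_sq = k_row[tile] + self.noise_var
            resid_k = k_row
            resid_y = reward
        else:
            l_vec = self._A[:t, tile]
            ell_sq = k_row[tile] + self.noise_var - l_vec @ l_vec
            resid_k = k_row - l_vec @ self._A[:t]
            resid_y = reward - l_vec @ self._w[:t]
        ell = np.sqrt(max(ell_sq, 1e-12))
        a_new = resid_k / ell
        w_new = resid_y / ell
        self._A[t] = a_new
        self._w[t] = w_new
        self._mean = self._mean + a_new * w_new
        self._sumsq = self._sumsq + a_new * a_new
        self._t = t + 1

    def posterior(self) -> Posterior:
        var = np.maximum(np.diag(self.kernel) - self._sumsq, 0.0)
        return Posterior(mean=self._mean.copy(), var=var)


class SequentialBMT:
    """Bayesian mean tracker: independent Kalman-filter updates per option."""

    def __init__(self, theta_err_sq: float,
                 prior_mean: float = DEFAULT_BMT_PRIOR_MEAN,
                 prior_var: float = DEFAULT_BMT_PRIOR_VAR):
        if not theta_err_sq > 0:
            raise ValueError(f"theta_err_sq must be positive, got {theta_err_sq}")
        self.theta_err_sq = theta_err_sq
        self._mean = np.full(N_OPTIONS, float(prior_mean))
        self._var = np.full(N_OPTIONS, float(prior_var))

    def update(self, tile: int, reward: float) -> None:
        gain = self._var[tile] / (self._var[tile] + self.theta_err_sq)
        self._mean[tile] += gain * (reward - self._mean[tile])
        self._var[tile] *= 1.0 - gain

    def posterior(self) -> Posterior:
        return Posterior(mean=self._mean.copy(), var=self._var.copy())


def gp_posterior(obs: Observations, lambda_: float,
                 noise_var: float = DEFAULT_OBS_NOISE_VAR) -> Posterior:
    """Exact GP posterior over all options given the observation history.

    With no observations this is the prior: mean 0 and variance k(x, x) = 1
    everywhere.  Posterior variance never exceeds the prior variance.
    """
    gp = SequentialGP(lambda_, noise_var)
    for tile, reward in zip(obs.tiles, obs.rewards):
        gp.update(int(tile), float(reward))
    return gp.posterior()


def bmt_update(post: Posterior, choice: int, reward: float,
               theta_err_sq: float) -> Posterior:
    """One Kalman-filter update; only the chosen option's mean/variance change.

    Kalman gain G = v / (v + theta_err_sq); the mean moves toward the reward
    by G times the prediction error and the variance shrinks by (1 - G).
    """
    if not theta_err_sq > 0:
        raise ValueError(f"theta_err_sq must be positive, got {theta_err_sq}")
    mean = post.mean.copy()
    var = post.var.copy()
    gain = var[choice] / (var[choice] + theta_err_sq)
    mean[choice] += gain * (reward - mean[choice])
    var[choice] *= 1.0 - gain
    return Posterior(mean=mean, var=var)


def bmt_posterior(obs: Observations, theta_err_sq: float,
                  prior_mean: float = DEFAULT_BMT_PRIOR_MEAN,
                  prior_var: float = DEFAULT_BMT_PRIOR_VAR) -> Posterior:
    """BMT posterior after sequentially processing the observation history."""
    bmt = SequentialBMT(theta_err_sq, prior_mean, prior_var)
    for tile, reward in zip(obs.tiles, obs.rewards):
        bmt.update(int(tile), float(reward))
    return bmt.posterior()


# ---------------------------------------------------------------------------
# Valuation and choice policies
# ---------------------------------------------------------------------------


def ucb_values(post: Posterior, beta: float) -> np.ndarray:
    """Upper-confidence-bound valuation q(x) = m(x) + beta * sqrt(v(x))."""
    if np.any(post.var < 0):
        raise ValueError("negative posterior variance")
    return post.mean + beta * np.sqrt(post.var)


def softmax_policy(values: np.ndarray, tau: float) -> np.ndarray:
    """Softmax choice probabilities p(x) proportional to exp(q(x) / tau).

    Computed in log-space with max-subtraction; tau -> infinity converges on
    the uniform random policy.
    """
    if not tau > 0:
        raise ValueError(f"tau must be strictly positive, got {tau}")
    z = np.asarray(values, dtype=float) / tau
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def epsilon_greedy_policy(values: np.ndarray, epsilon: float) -> np.ndarray:
    """Epsilon-greedy: mass epsilon spread uniformly, 1 - epsilon on the argmax.

    Ties at the maximum split the greedy mass equally (deterministic and
    order-independent).
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")
    values = np.asarray(values, dtype=float)
    n = values.size
    p = np.full(n, epsilon / n)
    top = values == values.max()
    p[top] += (1.0 - epsilon) / top.sum()
    return p


# ---------------------------------------------------------------------------
# Composed model
# ---------------------------------------------------------------------------


def make_learner(cfg: ModelConfig, params: ParameterSet,
                 kernel: np.ndarray | None = None):
    """Instantiate the sequential learner the model id calls for."""
    if cfg.model_id == LAMBDA_LESION:
        return SequentialBMT(params.theta_err_sq, cfg.bmt_prior_mean,
                             cfg.bmt_prior_var)
    return SequentialGP(params.lambda_, cfg.obs_noise_var, kernel=kernel)


def policy_probs(cfg: ModelConfig, params: ParameterSet,
                 post: Posterior) -> np.ndarray:
    """Choice probabilities from a posterior, per the model's valuation/policy."""
    beta = 0.0 if cfg.model_id == BETA_LESION else params.beta
    q = ucb_values(post, beta)
    if cfg.model_id == TAU_LESION:
        return epsilon_greedy_policy(q, params.epsilon)
    return softmax_policy(q, params.tau)


def model_predict(cfg: ModelConfig, params: ParameterSet,
                  obs: Observations) -> np.ndarray:
    """Predicted choice distribution over the 64 options given a history."""
    params.require(cfg.model_id)
    learner = make_learner(cfg, params)
    for tile, reward in zip(obs.tiles, obs.rewards):
        learner.update(int(tile), float(reward))
    return policy_probs(cfg, params, learner.posterior())


def predict_round_probs(cfg: ModelConfig, params: ParameterSet,
                        tiles: np.ndarray, rewards: np.ndarray,
                        kernel: np.ndarray | None = None) -> np.ndarray:
    """Choice probabilities for every trial of a round, conditioned on history.

    ``tiles``/``rewards`` are the full round including the initial reveal at
    position 0.  Row t of the result is the predicted distribution for the
    choice at position t + 1, conditioned on observations 0..t, so the
    result has len(tiles) - 1 rows.
    """
    params.require(cfg.model_id)
    tiles = np.asarray(tiles, dtype=int)
    rewards = np.asarray(rewards, dtype=float)
    n_pred = len(tiles) - 1
    learner = make_learner(cfg, params, kernel=kernel)
    out = np.empty((n_pred, N_OPTIONS))
    for t in range(n_pred):
        learner.update(int(tiles[t]), float(rewards[t]))
        out[t] = policy_probs(cfg, params, learner.posterior())
    return out


def lesion_config(cfg: ModelConfig, model_id: str) -> ModelConfig:
    """Same fixed settings, different model id."""
    return replace(cfg, model_id=model_id)
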