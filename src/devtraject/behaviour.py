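"""Behavioural summary statistics and the distance-vs-reward regression.

Summaries per participant: mean reward, per-trial learning and
running-maximum curves, unique options sampled per round, the proportions
of repeat / near / far transitions between consecutive choices, and mean
search distance.  A uniform-random baseline provides the chance-level
comparison.  A hierarchical Bayesian regression models search distance as
a function of the previous reward (standardized within the cohort) and age
group, with per-participant random intercepts and slopes; the random
effects are Gaussian and are integrated out analytically, so the sampler
only sees the group-level effects and variance components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agents, cohort, envgen
from .cohort import ParticipantRecord, RoundRecord
from .lifespan import McmcConfig, _run_ensemble, _split_rhat, _check_diagnostics

logger = logging.getLogger(__name__)

REPEAT, NEAR, FAR = "repeat", "near", "far"


def classify_choice(prev: tuple[int, int], cur: tuple[int, int]) -> str:
    """Classify a transition: repeat (same tile), near (Euclidean distance
    exactly 1, i.e. an orthogonal neighbour) or far (anything further;
    diagonal neighbours are far)."""
    for col, row in (prev, cur):
        if not (0 <= col < envgen.GRID_SIZE and 0 <= row < envgen.GRID_SIZE):
            raise ValueError(f"tile ({col}, {row}) off the lattice")
    d2 = (prev[0] - cur[0]) ** 2 + (prev[1] - cur[1]) ** 2
    if d2 == 0:
        return REPEAT
    if d2 == 1:
        return NEAR
    return FAR


def _round_transitions(rnd: RoundRecord) -> tuple[np.ndarray, np.ndarray]:
    """Distances and previous rewards for transitions among the choices.

    The initial reveal is excluded: transition t goes from choice t to
    choice t + 1, so a 25-choice round yields 24 transitions.
    """
    tiles = rnd.tiles[1:]
    cols = tiles % envgen.GRID_SIZE
    rows = tiles // envgen.GRID_SIZE
    dist = np.sqrt(np.diff(cols) ** 2 + np.diff(rows) ** 2)
    prev_reward = rnd.rewards_raw[1:-1]
    return dist, prev_reward


@dataclass
class BehaviourSummary:
    """Participant-level metrics, per-trial curves and group aggregates."""

    participant_table: pd.DataFrame
    curves: pd.DataFrame          # participant_id x trial: reward, running max
    group_table: pd.DataFrame


def behaviour_summary(records: list[ParticipantRecord]) -> BehaviourSummary:
    """All per-participant behavioural metrics plus age-group aggregates.

    Unique options count distinct tiles among the round's choices (reveal
    excluded); repeat/near/far proportions and mean search distance are
    over transitions between consecutive choices.  The running-maximum
    curve includes the revealed tile as the starting maximum.
    """
    rows, curve_rows = [], []
    for p in records:
        if not p.rounds:
            raise ValueError(f"participant {p.participant_id} has no rounds")
        n_trials = len(p.rounds[0]) - 1
        reward_curve = np.zeros(n_trials + 1)
        max_curve = np.zeros(n_trials + 1)
        unique_counts, dists = [], []
        for rnd in p.rounds:
            if len(rnd) != n_trials + 1:
                raise ValueError(
                    f"participant {p.participant_id}: inconsistent round length")
            reward_curve += rnd.rewards_raw
            max_curve += np.maximum.accumulate(rnd.rewards_raw)
            unique_counts.append(len(np.unique(rnd.tiles[1:])))
            dists.append(_round_transitions(rnd)[0])
        dists = np.concatenate(dists)
        n_rounds = len(p.rounds)
        d2 = dists**2
        prop_repeat = float((d2 == 0).mean())
        prop_near = float(np.isclose(d2, 1.0).mean())
        prop_far = 1.0 - prop_repeat - prop_near
        rows.append({
            "participant_id": p.participant_id, "age": p.age,
            "age_group": p.age_group, "experiment": p.experiment,
            "mean_reward": reward_curve[1:].sum() / (n_rounds * n_trials),
            "mean_unique": float(np.mean(unique_counts)),
            "prop_repeat": prop_repeat, "prop_near": prop_near,
            "prop_far": prop_far,
            "mean_distance": float(dists.mean()),
        })
        for t in range(n_trials + 1):
            curve_rows.append({
                "participant_id": p.participant_id, "age_group": p.age_group,
                "trial": t, "mean_reward": reward_curve[t] / n_rounds,
                "mean_max_reward": max_curve[t] / n_rounds,
            })
    table = pd.DataFrame(rows)
    if not np.allclose(
            table[["prop_repeat", "prop_near", "prop_far"]].sum(axis=1), 1):
        raise AssertionError("repeat/near/far proportions must sum to 1")
    group = (table.groupby("age_group", sort=False)
             [["mean_reward", "mean_unique", "prop_repeat", "prop_near",
               "prop_far", "mean_distance"]].mean().reset_index())
    return BehaviourSummary(participant_table=table,
                            curves=pd.DataFrame(curve_rows),
                            group_table=group)


def random_baseline(env_set: list[envgen.Environment], n_sim: int,
                    horizon: int = cohort.DEFAULT_HORIZON,
                    seed: int = 0) -> BehaviourSummary:
    """Behavioural metrics of the uniform-random policy over ``n_sim`` rounds."""
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    rng = np.random.default_rng(seed)
    rounds = []
    for _ in range(n_sim):
        env = env_set[rng.integers(len(env_set))]
        expected = envgen.rescale_for_round(env, envgen.draw_round_scaling(rng))
        tiles = rng.integers(envgen.N_OPTIONS, size=horizon + 1)
        rewards = envgen.draw_reward(expected[tiles], rng)
        rounds.append(RoundRecord(tiles=tiles, rewards_raw=rewards,
                                  scaling=envgen.RoundScaling(35.0),
                                  env_id=env.env_id))
    record = ParticipantRecord(participant_id="random-baseline", age=np.nan,
                               age_group="baseline", experiment="baseline",
                               rounds=rounds)
    return behaviour_summary([record])


# ---------------------------------------------------------------------------
# Distance ~ previous reward regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceRegressionPriors:
    effect_scale: float = 5.0       # normal(0, scale) on group intercepts/slopes
    sd_scale: float = 2.0           # half-normal on random-effect and residual SDs


@dataclass
class DistanceRegressionPosterior:
    """Posterior over group-level intercepts and slopes."""

    groups: list[str]
    intercept_draws: np.ndarray     # draws x groups
    slope_draws: np.ndarray         # draws x groups
    sd_draws: dict[str, np.ndarray]
    rhat: dict[str, float]

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, g in enumerate(self.groups):
            s = self.slope_draws[:, j]
            a = self.intercept_draws[:, j]
            rows.append({
                "age_group": g,
                "slope_mean": s.mean(),
                "slope_ci_low": np.quantile(s, 0.025),
                "slope_ci_high": np.quantile(s, 0.975),
                "intercept_mean": a.mean(),
            })
        return pd.DataFrame(rows)


def distance_reward_regression(
    records: list[ParticipantRecord],
    prior_cfg: DistanceRegressionPriors = DistanceRegressionPriors(),
    mcmc_cfg: McmcConfig = McmcConfig(),
    seed: int = 0,
) -> DistanceRegressionPosterior:
    """Hierarchical regression of search distance on previous reward x group.

    Distance (grid units) between consecutive choices is regressed on the
    previous reward, standardized across the whole cohort, with separate
    fixed intercepts and slopes per age group (cell-means coding of the
    group x reward interaction) and per-participant Gaussian random
    intercepts and slopes, which are marginalized analytically.
    """
    groups = list(dict.fromkeys(p.age_group for p in records))
    if len(groups) < 2:
        raise ValueError("need at least 2 age groups")
    g_index = {g: j for j, g in enumerate(groups)}

    all_prev = np.concatenate([
        _round_transitions(rnd)[1] for p in records for rnd in p.rounds])
    mu_r, sd_r = all_prev.mean(), max(all_prev.std(), 1e-9)

    # per-participant sufficient statistics for the marginal likelihood
    stats = []
    for p in records:
        dist, prev = [], []
        for rnd in p.rounds:
            d, r = _round_transitions(rnd)
            dist.append(d)
            prev.append(r)
        y = np.concatenate(dist)
        z = (np.concatenate(prev) - mu_r) / sd_r
        Z = np.column_stack([np.ones_like(z), z])
        stats.append({
            "g": g_index[p.age_group], "n": y.size,
            "ZtZ": Z.T @ Z, "Zty": Z.T @ y, "yty": float(y @ y),
        })
    n_groups = len(groups)
    g_codes = np.array([s["g"] for s in stats])
    n_obs = np.array([s["n"] for s in stats], dtype=float)
    ZtZ = np.stack([s["ZtZ"] for s in stats])       # P x 2 x 2
    Zty = np.stack([s["Zty"] for s in stats])       # P x 2
    yty = np.array([s["yty"] for s in stats])

    names = ([f"a{j}" for j in range(n_groups)]
             + [f"b{j}" for j in range(n_groups)]
             + ["log_sd_a", "log_sd_b", "log_sigma"])
    ndim = len(names)
    pr = prior_cfg

    def log_prob(theta: np.ndarray) -> float:
        a = theta[:n_groups]
        b = theta[n_groups:2 * n_groups]
        log_sd_a, log_sd_b, log_sigma = theta[-3:]
        if not all(-12 < v < 6 for v in (log_sd_a, log_sd_b, log_sigma)):
            return -np.inf
        sd_a, sd_b, sigma = np.exp([log_sd_a, log_sd_b, log_sigma])
        lp = -0.5 * ((a**2).sum() + (b**2).sum()) / pr.effect_scale**2
        lp += sum(-0.5 * s**2 / pr.sd_scale**2 + np.log(s)
                  for s in (sd_a, sd_b, sigma))
        gamma = np.column_stack([a[g_codes], b[g_codes]])      # P x 2
        # residual stats: r = y - Z gamma
        Ztr = Zty - np.einsum("pij,pj->pi", ZtZ, gamma)
        rtr = (yty - 2 * np.einsum("pi,pi->p", gamma, Zty)
               + np.einsum("pi,pij,pj->p", gamma, ZtZ, gamma))
        # Woodbury on Sigma = sigma^2 I + Z D Z', D = diag(sd_a^2, sd_b^2)
        d_inv = np.array([1.0 / sd_a**2, 1.0 / sd_b**2])
        M = ZtZ / sigma**2 + np.diag(d_inv)                    # P x 2 x 2
        det_m = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
        if np.any(det_m <= 0):
            return -np.inf
        inv_m = np.empty_like(M)
        inv_m[:, 0, 0] = M[:, 1, 1]
        inv_m[:, 1, 1] = M[:, 0, 0]
        inv_m[:, 0, 1] = -M[:, 0, 1]
        inv_m[:, 1, 0] = -M[:, 1, 0]
        inv_m /= det_m[:, None, None]
        quad = (rtr / sigma**2
                - np.einsum("pi,pij,pj->p", Ztr, inv_m, Ztr) / sigma**4)
        logdet = (n_obs * np.log(sigma**2) + np.log(det_m)
                  + np.log(sd_a**2) + np.log(sd_b**2))
        lp += -0.5 * (quad + logdet + n_obs * np.log(2 * np.pi)).sum()
        return float(lp)

    rng = np.random.default_rng(seed)
    p0 = 0.1 * rng.standard_normal((mcmc_cfg.n_walkers, ndim))
    p0[:, :n_groups] += np.concatenate([
        _round_transitions(rnd)[0] for p in records for rnd in p.rounds]).mean()
    p0[:, -3:] += np.log(0.5)
    chain = _run_ensemble(log_prob, p0, mcmc_cfg, seed)
    rhat = _split_rhat(chain, names)
    _check_diagnostics(rhat, mcmc_cfg, "distance-reward regression")
    flat = chain.reshape(-1, ndim)
    return DistanceRegressionPosterior(
        groups=groups,
        intercept_draws=flat[:, :n_groups],
        slope_draws=flat[:, n_groups:2 * n_groups],
        sd_draws={"sd_intercept": np.exp(flat[:, -3]),
                  "sd_slope": np.exp(flat[:, -2]),
                  "sigma": np.exp(flat[:, -1])},
        rhat=rhat)
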