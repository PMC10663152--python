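"""Synthetic cohorts: simulate the bandit task for age-dependent agents.

Ground-truth learning parameters follow piecewise-linear curves in age on
the log scale — a hinge with slope b1 before a changepoint omega and slope
b2 after, plus independent per-individual Gaussian noise.  Defaults mirror
the developmental pattern the analysis targets: generalization (lambda)
rises until about age 13, while the exploration bonus (beta) and decision
temperature (tau) fall steeply until about ages 9 and 8 respectively, all
plateauing afterwards (b2 = 0) at adult medians of 0.8, 0.3 and 0.03.

Each participant plays several rounds (default 10) of 25 choices plus one
initial random reveal, on environments drawn without replacement from a
shared set, with a fresh reward rescaling every round.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agents, envgen
from .agents import ModelConfig, ParameterSet
from .envgen import Environment, RoundScaling

#: Seven age bins spanning ages 5-55 (inclusive bounds in years).
AGE_GROUPS = (
    ("5-6", 5.0, 6.0),
    ("7-8", 7.0, 8.0),
    ("9-10", 9.0, 10.0),
    ("11-13", 11.0, 13.0),
    ("14-17", 14.0, 17.0),
    ("18-24", 18.0, 24.0),
    ("25-55", 25.0, 55.0),
)
AGE_GROUP_LABELS = tuple(g[0] for g in AGE_GROUPS)

DEFAULT_HORIZON = 25
DEFAULT_ROUNDS = 10
DEFAULT_GROUP_SIZE = 40

CSV_COLUMNS = [
    "participant_id", "age", "age_group", "experiment",
    "round", "trial", "x", "y", "reward_raw", "max_range",
]


def age_group_label(age: float) -> str:
    """Age-bin label for an age in years (gaps between bins round down)."""
    if not AGE_GROUPS[0][1] <= age <= AGE_GROUPS[-1][2]:
        raise ValueError(f"age {age} outside [5, 55]")
    for label, lo, hi in reversed(AGE_GROUPS):
        if age >= lo:
            return label
    raise AssertionError("unreachable")


def experiment_label(group_label: str) -> str:
    """Experiment assignment by age: youngest bin, middle bins, older bins.

    Mirrors a multi-study cohort where children, adolescents and adults were
    collected separately; exercises the regressions' random intercepts.
    """
    idx = AGE_GROUP_LABELS.index(group_label)
    return "exp1" if idx == 0 else ("exp2" if idx <= 3 else "exp3")


@dataclass(frozen=True)
class ParamAgeCurve:
    """Piecewise-linear age curve for one log-parameter.

    log-param(age) = b0 + b1 * (age - omega) if age <= omega
                     b0 + b2 * (age - omega) otherwise,
    plus N(0, sd^2) individual noise.  b0 is the log value at the
    changepoint, i.e. the adult plateau when b2 = 0.
    """

    b0: float
    b1: float
    b2: float = 0.0
    omega: float = 10.0
    sd: float = 0.5

    def __post_init__(self) -> None:
        if not 5.0 <= self.omega <= 55.0:
            raise ValueError(f"changepoint {self.omega} outside [5, 55]")
        if self.sd < 0:
            raise ValueError("individual SD must be non-negative")

    def mean_log(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        delta = age - self.omega
        return self.b0 + np.where(delta <= 0, self.b1 * delta, self.b2 * delta)


@dataclass(frozen=True)
class AgeCurveConfig:
    """Generative age curves for the three GP-UCB parameters."""

    lambda_: ParamAgeCurve = field(
        default_factory=lambda: ParamAgeCurve(
            b0=math.log(0.8), b1=0.08, b2=0.0, omega=12.7, sd=0.5)
    )
    beta: ParamAgeCurve = field(
        default_factory=lambda: ParamAgeCurve(
            b0=math.log(0.3), b1=-0.39, b2=0.0, omega=9.10, sd=0.5)
    )
    tau: ParamAgeCurve = field(
        default_factory=lambda: ParamAgeCurve(
            b0=math.log(0.03), b1=-0.59, b2=0.0, omega=7.74, sd=0.5)
    )

    def curves(self) -> dict[str, ParamAgeCurve]:
        return {"lambda_": self.lambda_, "beta": self.beta, "tau": self.tau}


def sample_age_params(age: float, cfg: AgeCurveConfig,
                      rng: np.random.Generator) -> ParameterSet:
    """Draw one participant's true (lambda, beta, tau) at a given age.

    Noise is independent across the three parameters; with sd = 0 the draw
    is the deterministic age curve.
    """
    values = {}
    for name, curve in cfg.curves().items():
        log_val = float(curve.mean_log(age)) + curve.sd * rng.standard_normal()
        values[name] = math.exp(log_val)
    return ParameterSet(**values)


@dataclass
class RoundRecord:
    """One round: tiles (flat indices, reveal first), raw rewards, scaling."""

    tiles: np.ndarray
    rewards_raw: np.ndarray
    scaling: RoundScaling
    env_id: str = "env"

    def __post_init__(self) -> None:
        self.tiles = np.asarray(self.tiles, dtype=int)
        self.rewards_raw = np.asarray(self.rewards_raw, dtype=float)
        if self.tiles.shape != self.rewards_raw.shape:
            raise ValueError("tiles and rewards must align")

    @property
    def rewards_norm(self) -> np.ndarray:
        return agents.normalize_rewards(self.rewards_raw)

    def __len__(self) -> int:
        return self.tiles.size


@dataclass
class ParticipantRecord:
    """A (possibly synthetic) participant and their per-round sequences."""

    participant_id: str
    age: float
    age_group: str
    experiment: str
    rounds: list[RoundRecord]
    true_params: ParameterSet | None = None


def _sample_index(probs: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(np.cumsum(probs), rng.random()))


def simulate_round(cfg: ModelConfig, params: ParameterSet, env: Environment,
                   scaling: RoundScaling, horizon: int,
                   rng: np.random.Generator,
                   kernel: np.ndarray | None = None) -> RoundRecord:
    """Play one round: a uniform random reveal, then ``horizon`` model choices.

    Every observation (reveal included) carries standard-normal reward noise
    and enters the model's history on the normalized scale.
    """
    params.require(cfg.model_id)
    expected = envgen.rescale_for_round(env, scaling)
    tiles = np.empty(horizon + 1, dtype=int)
    rewards = np.empty(horizon + 1)
    learner = agents.make_learner(cfg, params, kernel=kernel)
    tiles[0] = rng.integers(envgen.N_OPTIONS)
    rewards[0] = envgen.draw_reward(expected[tiles[0]], rng)
    learner.update(int(tiles[0]), rewards[0] / agents.MODEL_REWARD_SCALE)
    for t in range(1, horizon + 1):
        probs = agents.policy_probs(cfg, params, learner.posterior())
        tiles[t] = _sample_index(probs, rng)
        rewards[t] = envgen.draw_reward(expected[tiles[t]], rng)
        learner.update(int(tiles[t]), rewards[t] / agents.MODEL_REWARD_SCALE)
    return RoundRecord(tiles=tiles, rewards_raw=rewards, scaling=scaling,
                       env_id=env.env_id)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout: group sizes, rounds, horizon and generative age curves."""

    group_sizes: tuple[int, ...] = (DEFAULT_GROUP_SIZE,) * len(AGE_GROUPS)
    rounds_per_participant: int = DEFAULT_ROUNDS
    horizon: int = DEFAULT_HORIZON
    age_curves: AgeCurveConfig = field(default_factory=AgeCurveConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(AGE_GROUPS):
            raise ValueError(
                f"need {len(AGE_GROUPS)} group sizes, got {len(self.group_sizes)}"
            )


def generate_cohort(cohort_cfg: CohortConfig, env_set: list[Environment],
                    seed: int) -> list[ParticipantRecord]:
    """Simulate a full cohort; reproducible given the master seed.

    Each participant's rounds use environments drawn without replacement
    from ``env_set`` and an independent uniform max-range per round.
    """
    n_rounds = cohort_cfg.rounds_per_participant
    if n_rounds > len(env_set):
        raise ValueError(
            f"{n_rounds} rounds per participant but only {len(env_set)} "
            "environments to sample without replacement"
        )
    rng = np.random.default_rng(seed)
    # one kernel per unique lambda would not help here (lambda varies per
    # participant), but reuse within a participant does
    participants: list[ParticipantRecord] = []
    pid = 0
    for (label, lo, hi), size in zip(AGE_GROUPS, cohort_cfg.group_sizes):
        upper = min(hi + 1.0, AGE_GROUPS[-1][2])
        for _ in range(size):
            age = float(rng.uniform(lo, upper))
            params = sample_age_params(age, cohort_cfg.age_curves, rng)
            kernel = (envgen.kernel_matrix(params.lambda_)
                      if cohort_cfg.model.model_id != agents.LAMBDA_LESION else None)
            env_idx = rng.choice(len(env_set), size=n_rounds, replace=False)
            rounds = [
                simulate_round(
                    cohort_cfg.model, params, env_set[i],
                    envgen.draw_round_scaling(rng), cohort_cfg.horizon, rng,
                    kernel=kernel,
                )
                for i in env_idx
            ]
            participants.append(ParticipantRecord(
                participant_id=f"p{pid:04d}", age=age, age_group=label,
                experiment=experiment_label(label), rounds=rounds,
                true_params=params,
            ))
            pid += 1
    return participants


def cohort_to_frame(cohort: list[ParticipantRecord]) -> pd.DataFrame:
    """Long-format choice table (one row per observation, trial 0 = reveal)."""
    rows = []
    for p in cohort:
        for r_idx, rnd in enumerate(p.rounds):
            cols = rnd.tiles % envgen.GRID_SIZE
            rws = rnd.tiles // envgen.GRID_SIZE
            for t in range(len(rnd)):
                rows.append((p.participant_id, p.age, p.age_group, p.experiment,
                             r_idx, t, cols[t], rws[t], rnd.rewards_raw[t],
                             rnd.scaling.max_range))
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_cohort(frame: pd.DataFrame) -> list[ParticipantRecord]:
    """Rebuild participant records from a choice table (true params unknown)."""
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"choice table missing columns {missing}")
    participants = []
    for pid, pf in frame.groupby("participant_id", sort=False):
        rounds = []
        for _, rf in pf.groupby("round", sort=True):
            rf = rf.sort_values("trial")
            tiles = rf["y"].to_numpy(int) * envgen.GRID_SIZE + rf["x"].to_numpy(int)
            rounds.append(RoundRecord(
                tiles=tiles, rewards_raw=rf["reward_raw"].to_numpy(float),
                scaling=RoundScaling(max_range=float(rf["max_range"].iloc[0])),
            ))
        first = pf.iloc[0]
        participants.append(ParticipantRecord(
            participant_id=str(pid), age=float(first["age"]),
            age_group=str(first["age_group"]),
            experiment=str(first["experiment"]), rounds=rounds,
        ))
    return participants


def simulate_learning_curves(
    cfg: ModelConfig,
    params_by_group: dict[str, ParameterSet],
    env_set: list[Environment],
    n_sim: int,
    seed: int,
    horizon: int = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """Mean observed reward per trial per group over ``n_sim`` simulated rounds.

    Environments are drawn with replacement; trial 0 is the random reveal.
    Used to compare model-generated learning curves across age groups.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for group, params in params_by_group.items():
        kernel = (envgen.kernel_matrix(params.lambda_)
                  if cfg.model_id != agents.LAMBDA_LESION else None)
        rewards = np.zeros(horizon + 1)
        for _ in range(n_sim):
            env = env_set[rng.integers(len(env_set))]
            rnd = simulate_round(cfg, params, env,
                                 envgen.draw_round_scaling(rng), horizon, rng,
                                 kernel=kernel)
            rewards += rnd.rewards_raw
        frames.append(pd.DataFrame({
            "group": group, "trial": np.arange(horizon + 1),
            "mean_reward": rewards / n_sim,
        }))
    return pd.concat(frames, ignore_index=True)
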