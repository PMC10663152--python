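"""Fitness landscape over strategy space and stochastic optimization.

The strategy space is a log-spaced 3-D grid over (lambda, beta, tau),
bounded by Tukey fences around participant estimates.  Each cell's fitness
is the mean simulated reward of the GP-UCB model at those parameters.  Two
stochastic optimizers walk this landscape: simulated annealing (SA), which
proposes a random grid neighbour and accepts worse moves with probability
exp(delta / temp), and stochastic hill climbing (SHC), which picks among
all neighbours with probability proportional to exp(fitness / temp).  Both
are cooled over iterations by one of three schedules (fast 1/(1+i),
exponential exp(-i^(1/3)), linear 1-(i+1)/max_iter).

Fitness entering the acceptance/selection rules is min-max normalized to
[0, 1] so that optimization temperatures of order one are meaningful on
the 5..45 reward scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, envgen, lifespan
from .agents import GP_UCB, ModelConfig, ParameterSet

PARAM_NAMES = ("lambda_", "beta", "tau")
DEFAULT_RESOLUTION = 100        # full replication: 100^3 = 1e6 cells
DESK_RESOLUTION = 20            # desk-scale default used by tests/pipeline
DEFAULT_N_ITER = 1500
TEMP_FLOOR = 1e-6

SCHEDULES = ("fast", "exponential", "linear")


def tukey_fence_bounds(estimates, *, log: bool = True) -> tuple[float, float]:
    """Tukey fences (Q1 - 1.5 IQR, Q3 + 1.5 IQR) on log-estimates.

    Quartiles use linear interpolation.  Returns bounds in log units when
    ``log`` is on (the default) — the scale the parameter grid is built on.
    """
    values = np.asarray(estimates, dtype=float)
    if values.size < 4:
        raise ValueError(f"need at least 4 estimates, got {values.size}")
    if log:
        if np.any(values <= 0):
            raise ValueError("estimates must be positive for the log scale")
        values = np.log(values)
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def build_parameter_grid(bounds: dict[str, tuple[float, float]],
                         resolution: int = DEFAULT_RESOLUTION,
                         ) -> dict[str, np.ndarray]:
    """Log-equally-spaced axis values per parameter.

    ``bounds`` maps parameter name to (low, high) in log units.  With the
    default resolution of 100 points per axis the grid has one million
    combinations.
    """
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    axes = {}
    for name in PARAM_NAMES:
        lo, hi = bounds[name]
        if not lo < hi:
            raise ValueError(f"{name}: need low < high, got ({lo}, {hi})")
        axes[name] = np.exp(np.linspace(lo, hi, resolution))
    return axes


@dataclass
class FitnessLandscape:
    """Mean simulated reward over the (lambda, beta, tau) grid."""

    axes: dict[str, np.ndarray]
    fitness: np.ndarray
    rounds_per_cell: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        shape = tuple(len(self.axes[p]) for p in PARAM_NAMES)
        if self.fitness.shape != shape:
            raise ValueError(
                f"fitness shape {self.fitness.shape} != axes shape {shape}")
        for p in PARAM_NAMES:
            if np.any(np.diff(self.axes[p]) <= 0):
                raise ValueError(f"axis {p} must be strictly increasing")
        if not np.all(np.isfinite(self.fitness)):
            raise ValueError("non-finite fitness values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fitness.shape

    def normalized(self) -> np.ndarray:
        """Fitness min-max normalized to [0, 1] (constant maps to zeros)."""
        lo, hi = self.fitness.min(), self.fitness.max()
        if hi == lo:
            return np.zeros_like(self.fitness)
        return (self.fitness - lo) / (hi - lo)

    def params_at(self, idx: tuple[int, int, int]) -> ParameterSet:
        return ParameterSet(
            lambda_=float(self.axes["lambda_"][idx[0]]),
            beta=float(self.axes["beta"][idx[1]]),
            tau=float(self.axes["tau"][idx[2]]),
        )

    def nearest_index(self, params: ParameterSet) -> tuple[int, int, int]:
        """Snap a parameter point to the nearest grid cell in log-space.

        Distance ties resolve to the lower index; points outside the grid
        snap to the boundary.
        """
        idx = []
        for p in PARAM_NAMES:
            log_axis = np.log(self.axes[p])
            dist = np.abs(log_axis - np.log(getattr(params, p)))
            idx.append(int(np.argmin(dist)))  # argmin takes the lower tie
        return tuple(idx)

    def save(self, path: str | Path) -> None:
        payload = {
            "axes": {p: self.axes[p].tolist() for p in PARAM_NAMES},
            "fitness": self.fitness.ravel().tolist(),
            "shape": list(self.shape),
            "rounds_per_cell": self.rounds_per_cell,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "FitnessLandscape":
        payload = json.loads(Path(path).read_text())
        axes = {p: np.asarray(payload["axes"][p]) for p in PARAM_NAMES}
        fitness = np.asarray(payload["fitness"]).reshape(payload["shape"])
        return cls(axes=axes, fitness=fitness,
                   rounds_per_cell=payload.get("rounds_per_cell", 0),
                   seed=payload.get("seed"))


def compute_fitness_landscape(
    axes: dict[str, np.ndarray],
    env_set: list[envgen.Environment],
    rounds_per_cell: int = 10,
    horizon: int = cohort.DEFAULT_HORIZON,
    seed: int = 0,
    checkpoint_path: str | Path | None = None,
    checkpoint_every: int = 2000,
) -> FitnessLandscape:
    """Mean simulated GP-UCB reward for every grid cell.

    Each cell runs ``rounds_per_cell`` rounds, sampling an environment with
    replacement and a fresh reward rescaling per round; fitness is the mean
    observed reward over all trials (reveal included).  Cells draw from
    independent seeded streams, so results do not depend on evaluation
    order, and an interrupted run resumes from the checkpoint file.
    """
    shape = tuple(len(axes[p]) for p in PARAM_NAMES)
    fitness = np.full(shape, np.nan)
    start = 0
    if checkpoint_path is not None and Path(checkpoint_path).exists():
        saved = np.load(checkpoint_path)
        if tuple(saved["shape"]) == shape and int(saved["seed"]) == seed:
            fitness = saved["fitness"]
            start = int(saved["n_done"])
    cfg = ModelConfig(model_id=GP_UCB)
    kernels = {i: envgen.kernel_matrix(lam)
               for i, lam in enumerate(axes["lambda_"])}
    flat = fitness.ravel()
    for cell in range(start, flat.size):
        i, j, k = np.unravel_index(cell, shape)
        params = ParameterSet(lambda_=float(axes["lambda_"][i]),
                              beta=float(axes["beta"][j]),
                              tau=float(axes["tau"][k]))
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(cell,)))
        total = 0.0
        for _ in range(rounds_per_cell):
            env = env_set[rng.integers(len(env_set))]
            rnd = cohort.simulate_round(cfg, params, env,
                                        envgen.draw_round_scaling(rng),
                                        horizon, rng, kernel=kernels[i])
            total += rnd.rewards_raw.mean()
        flat[cell] = total / rounds_per_cell
        if checkpoint_path is not None and (cell + 1) % checkpoint_every == 0:
            np.savez(checkpoint_path, fitness=fitness, shape=np.array(shape),
                     seed=np.array(seed), n_done=np.array(cell + 1))
    return FitnessLandscape(axes=axes, fitness=fitness,
                            rounds_per_cell=rounds_per_cell, seed=seed)


def cooling_schedule(name: str, i: int, max_iter: int) -> float:
    """Optimization temperature at iteration ``i`` (0-based).

    fast: 1 / (1 + i); exponential: exp(-i^(1/3));
    linear: 1 - (i + 1) / max_iter, clamped below at 1e-6.
    """
    if not 0 <= i <= max_iter:
        raise ValueError(f"iteration {i} outside [0, {max_iter}]")
    if name == "fast":
        return 1.0 / (1.0 + i)
    if name == "exponential":
        return float(np.exp(-(i ** (1.0 / 3.0))))
    if name == "linear":
        return max(1.0 - (i + 1) / max_iter, TEMP_FLOOR)
    raise ValueError(f"unknown cooling schedule {name!r}; "
                     f"expected one of {SCHEDULES}")


def grid_neighbours(idx: tuple[int, int, int],
                    shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    """Von Neumann neighbours: one step along one axis, clipped at edges."""
    out = []
    for axis in range(3):
        for step in (-1, 1):
            cand = list(idx)
            cand[axis] += step
            if 0 <= cand[axis] < shape[axis]:
                out.append(tuple(cand))
    return out


def sa_step(norm_fitness: np.ndarray, current: tuple[int, int, int],
            temp: float, rng: np.random.Generator) -> tuple[int, int, int]:
    """One simulated-annealing step on normalized fitness.

    A uniformly random neighbour is proposed; moves that do not lower
    fitness are always accepted, worse moves with probability
    min(1, exp((new - old) / temp)).
    """
    neigh = grid_neighbours(current, norm_fitness.shape)
    proposal = neigh[rng.integers(len(neigh))]
    delta = norm_fitness[proposal] - norm_fitness[current]
    if delta >= 0:
        return proposal
    if temp <= 0:
        return current
    if rng.random() < np.exp(delta / temp):
        return proposal
    return current


def shc_step(norm_fitness: np.ndarray, current: tuple[int, int, int],
             temp: float, rng: np.random.Generator) -> tuple[int, int, int]:
    """One stochastic-hill-climbing step: a softmax over all neighbours.

    Each neighbour is selected with probability proportional to
    exp(fitness / temp); at temp -> 0 this is the argmax neighbour.
    """
    neigh = grid_neighbours(current, norm_fitness.shape)
    values = np.array([norm_fitness[n] for n in neigh])
    if temp <= 0:
        return neigh[int(values.argmax())]
    z = values / temp
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    return neigh[int(np.searchsorted(np.cumsum(p), rng.random()))]


@dataclass
class Trajectory:
    """One optimization run: grid indices, parameters and fitness per iteration."""

    indices: np.ndarray          # n_iter x 3
    params: np.ndarray           # n_iter x 3 (natural scale)
    fitness: np.ndarray          # n_iter (raw reward units)
    algorithm: str = "sa"
    schedule: str = "fast"
    init_id: str = ""

    def __len__(self) -> int:
        return len(self.indices)


def run_trajectories(algorithm: str, schedule: str,
                     init_sets: list[ParameterSet], n_iter: int,
                     landscape: FitnessLandscape,
                     seed: int = 0) -> list[Trajectory]:
    """Run one trajectory per initialization point.

    Iteration 0 is the (grid-snapped) initialization; each subsequent
    iteration i applies one step at temperature schedule(i - 1).  The
    iteration counter advances whether or not a move is accepted.
    """
    if algorithm not in ("sa", "shc"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    step_fn = sa_step if algorithm == "sa" else shc_step
    norm = landscape.normalized()
    param_grid = np.stack([landscape.axes[p] for p in PARAM_NAMES])
    out = []
    for t_id, init in enumerate(init_sets):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(t_id,)))
        idx = landscape.nearest_index(init)
        indices = np.empty((n_iter, 3), dtype=int)
        indices[0] = idx
        for i in range(1, n_iter):
            temp = cooling_schedule(schedule, i - 1, n_iter)
            idx = step_fn(norm, idx, temp, rng)
            indices[i] = idx
        params = np.column_stack([
            param_grid[a][indices[:, a]] for a in range(3)])
        fitness = landscape.fitness[
            indices[:, 0], indices[:, 1], indices[:, 2]]
        out.append(Trajectory(indices=indices, params=params, fitness=fitness,
                              algorithm=algorithm, schedule=schedule,
                              init_id=f"init{t_id:03d}"))
    return out


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    frames = []
    for t in trajectories:
        frames.append(pd.DataFrame({
            "trajectory_id": t.init_id, "algorithm": t.algorithm,
            "schedule": t.schedule, "iteration": np.arange(len(t)),
            "lambda": t.params[:, 0], "beta": t.params[:, 1],
            "tau": t.params[:, 2], "fitness": t.fitness,
        }))
    return pd.concat(frames, ignore_index=True)


def trajectory_changepoint(trajectories: list[Trajectory],
                           mcmc_cfg: lifespan.McmcConfig = lifespan.DEFAULT_MCMC,
                           seed: int = 0, subsample: int = 10,
                           ) -> dict[str, lifespan.ChangepointPosterior]:
    """Changepoint regression on algorithmic parameters over iterations.

    Reuses the age regression with the iteration index as the age-like
    predictor and log parameter values as the outcome; iterations are
    subsampled to keep the regression size manageable.
    """
    frame = trajectories_to_frame(trajectories)
    frame = frame[frame["iteration"] % subsample == 0]
    out = {}
    for i, (col, name) in enumerate(
            zip(("lambda", "beta", "tau"), PARAM_NAMES)):
        out[name] = lifespan.fit_changepoint(
            frame["iteration"].to_numpy(float), frame[col].to_numpy(float),
            experiment_ids=None, mcmc_cfg=mcmc_cfg, seed=seed + i,
            predictor_name="iteration")
    return out


@dataclass
class ConvergenceComparison:
    """Post-convergence human-vs-algorithm contrast for one parameter."""

    parameter: str
    n_matched: int
    u_statistic: float
    p_value: float
    rank_biserial: float        # >0: algorithm values higher than human
    human_median: float
    algorithm_median: float


def convergence_comparison(human_fits: pd.DataFrame, human_omega: dict[str, float],
                           trajectories: list[Trajectory],
                           traj_omega: dict[str, float],
                           seed: int = 0) -> list[ConvergenceComparison]:
    """Compare post-convergence parameter values, human vs algorithm.

    ``human_omega`` / ``traj_omega`` give, per parameter, the upper 95% CI
    of the respective changepoint estimate, used as convergence thresholds
    (ages above / iterations above).  A matched sample (equal-size random
    subsample without replacement) feeds a Mann-Whitney U test with a
    rank-biserial effect size.
    """
    from scipy.stats import mannwhitneyu

    traj_frame = trajectories_to_frame(trajectories)
    rng = np.random.default_rng(seed)
    out = []
    col_map = {"lambda_": "lambda", "beta": "beta", "tau": "tau"}
    for name in PARAM_NAMES:
        col = col_map[name]
        human_vals = human_fits.loc[
            human_fits["age"] > human_omega[name], col].dropna().to_numpy(float)
        algo_vals = traj_frame.loc[
            traj_frame["iteration"] > traj_omega[name], col].to_numpy(float)
        if human_vals.size == 0 or algo_vals.size == 0:
            raise ValueError(
                f"{name}: no values beyond the convergence threshold "
                f"(human n={human_vals.size}, algorithm n={algo_vals.size})")
        n = min(human_vals.size, algo_vals.size)
        human_sub = rng.choice(human_vals, size=n, replace=False)
        algo_sub = rng.choice(algo_vals, size=n, replace=False)
        res = mannwhitneyu(algo_sub, human_sub, alternative="two-sided")
        rank_biserial = 2.0 * res.statistic / (n * n) - 1.0
        out.append(ConvergenceComparison(
            parameter=name, n_matched=n, u_statistic=float(res.statistic),
            p_value=float(res.pvalue), rank_biserial=float(rank_biserial),
            human_median=float(np.median(human_sub)),
            algorithm_median=float(np.median(algo_sub))))
    return out
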