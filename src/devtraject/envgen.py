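"""Spatially correlated reward environments on an 8x8 lattice.

Expected rewards are draws from a zero-mean multivariate Gaussian whose
covariance is a radial-basis-function (RBF) kernel over tile coordinates,
min-max normalized to [0, 1] per environment.  At simulation time each round
rescales the unit grid to an effective reward range of 5..45: a maximum
range is drawn uniformly from [30, 40] and a constant shift of +5 keeps
observations away from zero.  Observed rewards are the expected value
corrupted by standard-normal noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

GRID_SIZE = 8
N_OPTIONS = GRID_SIZE * GRID_SIZE

#: (col, row) coordinate of every tile, row-major: index = row * 8 + col.
COORDS = np.array(
    [(col, row) for row in range(GRID_SIZE) for col in range(GRID_SIZE)],
    dtype=float,
)

#: Pairwise squared Euclidean distances between all 64 tiles.
SQDIST = ((COORDS[:, None, :] - COORDS[None, :, :]) ** 2).sum(-1)

DEFAULT_GEN_LAMBDA = 4.0  # smooth condition; the rough condition uses 1.0
ROUND_SHIFT = 5.0
MAX_RANGE_LOW = 30.0
MAX_RANGE_HIGH = 40.0
JITTER = 1e-8


@dataclass(frozen=True)
class KernelSpec:
    """RBF kernel with length-scale ``lambda_`` (grid units)."""

    lambda_: float = DEFAULT_GEN_LAMBDA

    def __post_init__(self) -> None:
        if not np.isfinite(self.lambda_) or self.lambda_ <= 0:
            raise ValueError(f"length-scale must be positive, got {self.lambda_}")


@dataclass(frozen=True)
class RoundScaling:
    """Per-round reward rescaling: expected = shift + unit_value * max_range."""

    max_range: float
    shift: float = ROUND_SHIFT

    def __post_init__(self) -> None:
        if not (MAX_RANGE_LOW <= self.max_range <= MAX_RANGE_HIGH):
            raise ValueError(
                f"max_range must lie in [{MAX_RANGE_LOW}, {MAX_RANGE_HIGH}], "
                f"got {self.max_range}"
            )


@dataclass
class Environment:
    """One 8x8 reward environment, unit-normalized.

    ``grid_values`` holds the 64 expected rewards in row-major order
    (index = row * 8 + col) with min 0 and max 1.
    """

    grid_values: np.ndarray
    gen_lambda: float = DEFAULT_GEN_LAMBDA
    env_id: str = field(default="env")

    def __post_init__(self) -> None:
        self.grid_values = np.asarray(self.grid_values, dtype=float).ravel()
        if self.grid_values.size != N_OPTIONS:
            raise ValueError(
                f"environment needs {N_OPTIONS} values, got {self.grid_values.size}"
            )
        if not np.all(np.isfinite(self.grid_values)):
            raise ValueError("environment grid contains non-finite values")
        lo, hi = self.grid_values.min(), self.grid_values.max()
        if not (np.isclose(lo, 0.0) and np.isclose(hi, 1.0)):
            raise ValueError(f"grid must be min-max normalized, got range [{lo}, {hi}]")


def tile_index(col: int, row: int) -> int:
    """Row-major flat index of tile (col, row)."""
    if not (0 <= col < GRID_SIZE and 0 <= row < GRID_SIZE):
        raise ValueError(f"tile ({col}, {row}) off the {GRID_SIZE}x{GRID_SIZE} lattice")
    return row * GRID_SIZE + col


def tile_coord(index: int) -> tuple[int, int]:
    """(col, row) coordinate of a flat tile index."""
    if not 0 <= index < N_OPTIONS:
        raise ValueError(f"tile index {index} out of range")
    return index % GRID_SIZE, index // GRID_SIZE


def rbf_kernel(x, x2, spec: KernelSpec) -> float:
    """Similarity k(x, x') = exp(-||x - x'||^2 / (2 lambda^2)).

    ``x`` and ``x2`` are (col, row) coordinates; distance is Euclidean.
    Returns 1 exactly when the tiles coincide and decays towards 0 with
    distance, faster for smaller length-scales.
    """
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    d2 = float(((x - x2) ** 2).sum())
    return float(np.exp(-d2 / (2.0 * spec.lambda_**2)))


def kernel_matrix(lambda_: float, sqdist: np.ndarray = SQDIST) -> np.ndarray:
    """Full RBF kernel matrix over the lattice (64 x 64 by default)."""
    if lambda_ <= 0:
        raise ValueError(f"length-scale must be positive, got {lambda_}")
    return np.exp(-sqdist / (2.0 * lambda_**2))


def sample_environment(
    spec: KernelSpec, seed: int | np.random.Generator, env_id: str = "env"
) -> Environment:
    """Draw one environment from N(0, K) and min-max normalize it.

    The covariance gets a small diagonal jitter before the Cholesky
    factorization for numerical stability.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cov = kernel_matrix(spec.lambda_) + JITTER * np.eye(N_OPTIONS)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"kernel covariance (lambda={spec.lambda_}) not positive definite "
            f"after jitter {JITTER}"
        ) from exc
    raw = chol @ rng.standard_normal(N_OPTIONS)
    lo, hi = raw.min(), raw.max()
    grid = (raw - lo) / (hi - lo)
    return Environment(grid_values=grid, gen_lambda=spec.lambda_, env_id=env_id)


def rescale_for_round(env: Environment, scaling: RoundScaling) -> np.ndarray:
    """Expected rewards on the effective scale: shift + grid * max_range.

    With unit-normalized grids the per-round minimum is exactly ``shift``
    (5) and the maximum is ``shift + max_range`` (at most 45).
    """
    return scaling.shift + env.grid_values * scaling.max_range


def draw_reward(expected, rng: np.random.Generator):
    """Observed reward: expected value plus standard-normal noise."""
    expected = np.asarray(expected, dtype=float)
    noise = rng.standard_normal(expected.shape if expected.shape else None)
    out = expected + noise
    return float(out) if np.ndim(out) == 0 else out


def draw_round_scaling(rng: np.random.Generator) -> RoundScaling:
    """Sample the per-round maximum range from U(30, 40)."""
    return RoundScaling(max_range=float(rng.uniform(MAX_RANGE_LOW, MAX_RANGE_HIGH)))


def generate_environment_set(
    n: int = 40,
    spec: KernelSpec | None = None,
    seed: int = 0,
) -> list[Environment]:
    """Generate ``n`` independent environments (default 40, the task's set size)."""
    if n < 1:
        raise ValueError(f"need at least one environment, got n={n}")
    spec = spec or KernelSpec()
    rng = np.random.default_rng(seed)
    return [
        sample_environment(spec, rng, env_id=f"env{i:03d}") for i in range(n)
    ]


def save_environments(envs: list[Environment], path: str | Path) -> None:
    """Write an environment set to JSON (row-major grids, full precision)."""
    payload = [
        {
            "env_id": e.env_id,
            "gen_lambda": e.gen_lambda,
            "grid": e.grid_values.tolist(),
        }
        for e in envs
    ]
    Path(path).write_text(json.dumps(payload))


def load_environments(path: str | Path) -> list[Environment]:
    """Read an environment set written by :func:`save_environments`."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"environment file {path} is not valid JSON: {exc}") from exc
    envs = []
    for i, entry in enumerate(payload):
        for key in ("env_id", "gen_lambda", "grid"):
            if key not in entry:
                raise ValueError(
                    f"environment file {path}, entry {i}: missing field '{key}'"
                )
        envs.append(
            Environment(
                grid_values=np.asarray(entry["grid"], dtype=float),
                gen_lambda=float(entry["gen_lambda"]),
                env_id=str(entry["env_id"]),
            )
        )
    return envs
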