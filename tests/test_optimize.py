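"""Fitness landscape, cooling schedules, SA/SHC steps and trajectories."""

import numpy as np
import pandas as pd
import pytest

from devtraject import optimize
from devtraject.agents import ParameterSet
from devtraject.lifespan import McmcConfig
from devtraject.optimize import (FitnessLandscape, Trajectory,
                                 build_parameter_grid, cooling_schedule,
                                 convergence_comparison, grid_neighbours,
                                 run_trajectories, sa_step, shc_step,
                                 tukey_fence_bounds)


class TestTukeyFence:
    def test_constant_sample_degenerate(self):
        lo, hi = tukey_fence_bounds([2.0, 2.0, 2.0, 2.0])
        assert lo == hi == pytest.approx(np.log(2.0))

    def test_known_quartiles(self):
        # log-values 0..4: Q1 = 1, Q3 = 3, fence (-2, 6)
        lo, hi = tukey_fence_bounds(np.exp([0.0, 1.0, 2.0, 3.0, 4.0]))
        assert lo == pytest.approx(-2.0)
        assert hi == pytest.approx(6.0)

    def test_outlier_widens_fence(self):
        base = np.exp([0.0, 1.0, 2.0, 3.0, 4.0])
        lo1, hi1 = tukey_fence_bounds(base)
        lo2, hi2 = tukey_fence_bounds(np.append(base, np.exp(12.0)))
        assert hi2 > hi1
        assert lo2 <= lo1 + 1e-12 or hi2 - lo2 > hi1 - lo1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tukey_fence_bounds([1.0, 2.0, 3.0])


class TestParameterGrid:
    bounds = {"lambda_": (-2.0, 1.5), "beta": (-3.0, 1.0), "tau": (-5.0, 0.0)}

    def test_full_resolution_is_one_million_cells(self):
        axes = build_parameter_grid(self.bounds, resolution=100)
        assert np.prod([len(axes[p]) for p in optimize.PARAM_NAMES]) == 10**6

    def test_resolution_two_gives_endpoints(self):
        axes = build_parameter_grid(self.bounds, resolution=2)
        assert axes["lambda_"][0] == pytest.approx(np.exp(-2.0))
        assert axes["lambda_"][-1] == pytest.approx(np.exp(1.5))

    def test_log_spacing_constant_ratio(self):
        axes = build_parameter_grid(self.bounds, resolution=13)
        for p in optimize.PARAM_NAMES:
            ratios = axes[p][1:] / axes[p][:-1]
            assert np.allclose(ratios, ratios[0])


class TestCoolingSchedules:
    def test_fast(self):
        assert cooling_schedule("fast", 0, 100) == 1.0
        assert cooling_schedule("fast", 1, 100) == 0.5

    def test_exponential(self):
        assert cooling_schedule("exponential", 0, 100) == pytest.approx(1.0)
        assert cooling_schedule("exponential", 27, 100) == \
            pytest.approx(np.exp(-3.0))

    def test_linear_clamped_at_floor(self):
        assert cooling_schedule("linear", 99, 100) == pytest.approx(1e-6)
        assert cooling_schedule("linear", 0, 100) == pytest.approx(0.99)

    def test_unknown_schedule(self):
        with pytest.raises(ValueError, match="unknown cooling schedule"):
            cooling_schedule("quadratic", 0, 10)


def toy_landscape(shape=(5, 5, 5), seed=0):
    rng = np.random.default_rng(seed)
    axes = {p: np.exp(np.linspace(-2, 1, shape[i]))
            for i, p in enumerate(optimize.PARAM_NAMES)}
    fitness = rng.uniform(10, 40, size=shape)
    return FitnessLandscape(axes=axes, fitness=fitness)


class TestSteps:
    def test_neighbour_counts(self):
        assert len(grid_neighbours((0, 0, 0), (5, 5, 5))) == 3
        assert len(grid_neighbours((2, 2, 2), (5, 5, 5))) == 6
        assert len(grid_neighbours((0, 2, 4), (5, 5, 5))) == 4

    def test_sa_always_accepts_improvement(self):
        scape = toy_landscape()
        norm = scape.normalized()
        rng = np.random.default_rng(1)
        for _ in range(50):
            cur = tuple(rng.integers(0, 5, size=3))
            nxt = sa_step(norm, cur, temp=1e-12, rng=rng)
            assert norm[nxt] >= norm[cur] or nxt == cur

    def test_sa_greedy_fitness_never_decreases(self):
        scape = toy_landscape(seed=2)
        norm = scape.normalized()
        rng = np.random.default_rng(3)
        cur = (2, 2, 2)
        history = [norm[cur]]
        for _ in range(200):
            cur = sa_step(norm, cur, temp=0.0, rng=rng)
            history.append(norm[cur])
        assert np.all(np.diff(history) >= 0)

    def test_sa_acceptance_probability_closed_form(self):
        """A worse move with delta = -temp is accepted with prob exp(-1)."""
        norm = np.zeros((3, 1, 1))
        norm[0, 0, 0] = 0.7   # uphill neighbour: always accepted
        norm[1, 0, 0] = 0.5   # current state
        norm[2, 0, 0] = 0.3   # downhill neighbour: delta = -temp
        rng = np.random.default_rng(4)
        accepted = sum(
            sa_step(norm, (1, 0, 0), temp=0.2, rng=rng) != (1, 0, 0)
            for _ in range(4000))
        # neighbours of (1,0,0): (0,..) with delta +0.2 (always accepted) and
        # (2,..) with delta -0.2 accepted w.p. exp(-1)
        expected = 0.5 + 0.5 * np.exp(-1.0)
        assert accepted / 4000 == pytest.approx(expected, abs=0.03)

    def test_shc_zero_temperature_argmax(self):
        scape = toy_landscape(seed=5)
        norm = scape.normalized()
        rng = np.random.default_rng(6)
        cur = (2, 2, 2)
        neigh = grid_neighbours(cur, norm.shape)
        best = max(neigh, key=lambda n: norm[n])
        for _ in range(20):
            assert shc_step(norm, cur, temp=1e-15, rng=rng) == best

    def test_shc_two_point_softmax(self):
        norm = np.zeros((3, 1, 1))
        norm[0, 0, 0] = 0.2
        norm[2, 0, 0] = 0.4
        rng = np.random.default_rng(7)
        picks = [shc_step(norm, (1, 0, 0), temp=0.1, rng=rng)
                 for _ in range(4000)]
        p_better = np.mean([p == (2, 0, 0) for p in picks])
        assert p_better == pytest.approx(1 / (1 + np.exp(-2.0)), abs=0.025)

    def test_flat_fitness_random_walk_symmetry(self):
        norm = np.zeros((7, 7, 7))
        rng = np.random.default_rng(8)
        for step_fn in (sa_step, shc_step):
            disp = []
            for _ in range(300):
                cur = (3, 3, 3)
                for _ in range(4):
                    cur = step_fn(norm, cur, temp=0.5, rng=rng)
                disp.append(np.array(cur) - 3)
            mean_disp = np.mean(disp, axis=0)
            assert np.all(np.abs(mean_disp) < 0.2)


class TestLandscape:
    def test_save_load_round_trip(self, tmp_path):
        scape = toy_landscape(seed=9)
        path = tmp_path / "scape.json"
        scape.save(path)
        loaded = FitnessLandscape.load(path)
        assert np.array_equal(loaded.fitness, scape.fitness)
        for p in optimize.PARAM_NAMES:
            assert np.array_equal(loaded.axes[p], scape.axes[p])

    def test_nearest_index_snapping_and_tie_break(self):
        scape = toy_landscape()
        axis = scape.axes["lambda_"]
        exact = ParameterSet(lambda_=float(axis[2]),
                             beta=float(scape.axes["beta"][0]),
                             tau=float(scape.axes["tau"][4]))
        assert scape.nearest_index(exact) == (2, 0, 4)
        # geometric midpoint in log space: tie resolves to the lower index
        mid = float(np.exp((np.log(axis[1]) + np.log(axis[2])) / 2))
        tie = ParameterSet(lambda_=mid, beta=float(scape.axes["beta"][0]),
                           tau=float(scape.axes["tau"][0]))
        assert scape.nearest_index(tie)[0] == 1
        # out-of-range points snap to the boundary
        out = ParameterSet(lambda_=1e-9, beta=1e9, tau=1.0)
        idx = scape.nearest_index(out)
        assert idx[0] == 0 and idx[1] == len(scape.axes["beta"]) - 1

    def test_small_landscape_monotone_in_tau_and_checkpoint(
            self, small_envs, tmp_path):
        axes = {
            "lambda_": np.array([0.8]),
            "beta": np.array([0.3]),
            "tau": np.exp(np.linspace(np.log(0.02), np.log(20.0), 4)),
        }
        scape = optimize.compute_fitness_landscape(
            axes, small_envs, rounds_per_cell=30, horizon=15, seed=1)
        fitness = scape.fitness[0, 0]
        assert fitness[0] > fitness[-1]  # greedy beats near-random sampling
        # checkpoint resume must reproduce the same landscape
        ck = tmp_path / "ck.npz"
        partial = np.full(scape.fitness.shape, np.nan)
        partial.ravel()[:2] = scape.fitness.ravel()[:2]
        np.savez(ck, fitness=partial, shape=np.array(scape.fitness.shape),
                 seed=np.array(1), n_done=np.array(2))
        resumed = optimize.compute_fitness_landscape(
            axes, small_envs, rounds_per_cell=30, horizon=15, seed=1,
            checkpoint_path=ck)
        assert np.array_equal(resumed.fitness, scape.fitness)


class TestTrajectories:
    def test_length_and_neighbour_moves(self):
        scape = toy_landscape(seed=10)
        inits = [ParameterSet(lambda_=0.5, beta=0.5, tau=0.5)] * 3
        trajs = run_trajectories("sa", "fast", inits, 50, scape, seed=2)
        assert len(trajs) == 3
        for t in trajs:
            assert len(t) == 50
            steps = np.abs(np.diff(t.indices, axis=0)).sum(axis=1)
            assert np.all(steps <= 1)  # stay or move to a grid neighbour

    def test_algorithm_validation(self):
        scape = toy_landscape()
        with pytest.raises(ValueError):
            run_trajectories("sgd", "fast",
                             [ParameterSet(lambda_=1, beta=1, tau=1)],
                             10, scape, seed=0)


def synthetic_trajectories(n_traj=6, n_iter=400, seed=0):
    """Trajectories whose lambda rises then plateaus, beta/tau fall."""
    rng = np.random.default_rng(seed)
    out = []
    for t_id in range(n_traj):
        it = np.arange(n_iter)
        hinge = np.minimum(it, 100)
        lam = np.exp(-1.0 + 0.01 * hinge + rng.normal(0, 0.05, n_iter))
        beta = np.exp(0.0 - 0.012 * hinge + rng.normal(0, 0.05, n_iter))
        tau = np.exp(-1.0 - 0.02 * hinge + rng.normal(0, 0.05, n_iter))
        params = np.column_stack([lam, beta, tau])
        out.append(Trajectory(indices=np.zeros((n_iter, 3), dtype=int),
                              params=params, fitness=np.zeros(n_iter),
                              algorithm="shc", schedule="fast",
                              init_id=f"init{t_id}"))
    return out


class TestTrajectoryChangepoint:
    def test_recovers_direction_of_parameter_drift(self):
        trajs = synthetic_trajectories()
        posts = optimize.trajectory_changepoint(
            trajs, mcmc_cfg=McmcConfig(n_steps=1500, n_burn=700), seed=1,
            subsample=10)
        assert np.mean(posts["lambda_"].draws["b1"]) > 0
        assert np.mean(posts["beta"].draws["b1"]) < 0
        assert np.mean(posts["tau"].draws["b1"]) < 0
        for name in ("lambda_", "beta", "tau"):
            lo, hi = posts[name].ci("b2")
            assert lo < 0.005 and hi > -0.005  # plateau: b2 near zero


class TestConvergenceComparison:
    def _human_fits(self, rng, n=60, shift=0.0):
        return pd.DataFrame({
            "age": rng.uniform(5, 55, size=n),
            "lambda": np.exp(rng.normal(-0.2 + shift, 0.3, size=n)),
            "beta": np.exp(rng.normal(-1.2, 0.3, size=n)),
            "tau": np.exp(rng.normal(-3.5, 0.3, size=n)),
        })

    def test_null_comparison_not_significant(self):
        rng = np.random.default_rng(1)
        fits = self._human_fits(rng)
        trajs = []
        for i in range(4):
            n_iter = 200
            params = np.column_stack([
                np.exp(rng.normal(-0.2, 0.3, n_iter)),
                np.exp(rng.normal(-1.2, 0.3, n_iter)),
                np.exp(rng.normal(-3.5, 0.3, n_iter)),
            ])
            trajs.append(Trajectory(indices=np.zeros((n_iter, 3), int),
                                    params=params, fitness=np.zeros(n_iter),
                                    init_id=f"i{i}"))
        omega_h = {p: 12.0 for p in optimize.PARAM_NAMES}
        omega_t = {p: 50.0 for p in optimize.PARAM_NAMES}
        res = convergence_comparison(fits, omega_h, trajs, omega_t, seed=2)
        for comp in res:
            assert abs(comp.rank_biserial) < 0.25
            assert comp.p_value > 0.01

    def test_injected_shift_detected(self):
        rng = np.random.default_rng(3)
        fits = self._human_fits(rng)
        trajs = []
        for i in range(4):
            n_iter = 200
            params = np.column_stack([
                np.exp(rng.normal(0.8, 0.3, n_iter)),   # +1 log-unit lambda
                np.exp(rng.normal(-1.2, 0.3, n_iter)),
                np.exp(rng.normal(-3.5, 0.3, n_iter)),
            ])
            trajs.append(Trajectory(indices=np.zeros((n_iter, 3), int),
                                    params=params, fitness=np.zeros(n_iter),
                                    init_id=f"i{i}"))
        omega_h = {p: 12.0 for p in optimize.PARAM_NAMES}
        omega_t = {p: 50.0 for p in optimize.PARAM_NAMES}
        res = convergence_comparison(fits, omega_h, trajs, omega_t, seed=4)
        lam = next(c for c in res if c.parameter == "lambda_")
        assert lam.rank_biserial > 0.5
        assert lam.p_value < 0.001

    def test_matched_sample_size_is_min_count(self):
        rng = np.random.default_rng(5)
        fits = self._human_fits(rng, n=30)
        trajs = synthetic_trajectories(n_traj=2, n_iter=100, seed=6)
        omega_h = {p: 25.0 for p in optimize.PARAM_NAMES}
        omega_t = {p: 80.0 for p in optimize.PARAM_NAMES}
        res = convergence_comparison(fits, omega_h, trajs, omega_t, seed=7)
        n_human = (fits["age"] > 25.0).sum()
        n_algo = 2 * (100 - 81)
        for comp in res:
            assert comp.n_matched == min(n_human, n_algo)

    def test_empty_threshold_set_raises(self):
        rng = np.random.default_rng(8)
        fits = self._human_fits(rng, n=10)
        trajs = synthetic_trajectories(n_traj=1, n_iter=50, seed=9)
        omega_h = {p: 60.0 for p in optimize.PARAM_NAMES}
        omega_t = {p: 10.0 for p in optimize.PARAM_NAMES}
        with pytest.raises(ValueError, match="convergence threshold"):
            convergence_comparison(fits, omega_h, trajs, omega_t, seed=10)
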