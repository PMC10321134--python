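"""Swarm optimizer: chaotic map, inertia schedule, greedy elitism, search."""

import numpy as np
import pytest

from oedl import learners
from oedl.bboa import (
    BBOAConfig,
    MemoizedFitness,
    chaotic_sequence,
    decode_position,
    inertia_weight,
    init_population,
    optimize,
    search_architecture,
    step,
)


def box(dims=2, lo=0, hi=100, **kw):
    return BBOAConfig(dims=dims, lower=[lo] * dims, upper=[hi] * dims, **kw)


class TestChaoticMap:
    def test_zero_is_fixed_point(self):
        assert chaotic_sequence(0.0, 2.3, 5).tolist() == [0.0] * 5

    def test_hand_iterated_three_steps(self):
        a, m = 2.3, 0.7
        expect = []
        for _ in range(3):
            m = a * m * m * np.sin(np.pi * m)
            expect.append(m)
        np.testing.assert_allclose(chaotic_sequence(0.7, 2.3, 3), expect, atol=1e-15)

    def test_empty_length(self):
        assert chaotic_sequence(0.5, 2.3, 0).size == 0


class TestInit:
    def test_positions_within_bounds_and_integral(self):
        cfg = box(3, 1, 100, pop_size=30, seed=2)
        state = init_population(cfg)
        assert (state.positions >= 1).all() and (state.positions <= 100).all()
        assert np.array_equal(state.positions, np.round(state.positions))
        assert (state.velocities == 0).all()

    def test_dispersion(self):
        distinct = []
        for seed in range(5):
            state = init_population(box(2, 1, 100, pop_size=30, seed=seed))
            distinct.append(len(np.unique(state.positions[:, 0])))
        assert np.median(distinct) >= 5

    def test_seed_determinism(self):
        a = init_population(box(2, seed=5))
        b = init_population(box(2, seed=5))
        assert np.array_equal(a.positions, b.positions)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            BBOAConfig(dims=1, lower=[5], upper=[5])


class TestStep:
    def test_inertia_endpoints_exact(self):
        cfg = box(2, n_iter=100)
        assert inertia_weight(0, cfg) == cfg.w_s
        assert inertia_weight(cfg.n_iter, cfg) == cfg.w_e

    def test_global_best_never_degrades(self):
        cfg = box(2, seed=3, n_iter=30)
        fn = MemoizedFitness(lambda p: -((p[0] - 42) ** 2 + (p[1] - 17) ** 2))
        state = init_population(cfg, fn)
        rng = np.random.default_rng(0)
        for _ in range(30):
            before = state.gbest_fit
            step(state, cfg, fn, rng)
            assert state.gbest_fit >= before

    def test_zero_velocity_zero_attraction_is_stationary(self):
        cfg = box(2, seed=1, ef1=0.0, ef2=0.0, w_s=0.9, w_e=0.4)
        fn = lambda p: 0.0
        state = init_population(cfg, fn)
        pos = state.positions.copy()
        step(state, cfg, fn, np.random.default_rng(0))
        assert np.array_equal(state.positions, pos)

    def test_non_finite_fitness_names_galaxy(self):
        cfg = box(1, seed=0)
        state = init_population(cfg, lambda p: 0.0)
        with pytest.raises(ValueError, match="galaxy"):
            step(state, cfg, lambda p: np.nan, np.random.default_rng(0))


class TestOptimize:
    def test_concave_integer_objective_found(self):
        hits = 0
        for seed in range(20):
            cfg = box(1, 0, 100, pop_size=20, n_iter=100, seed=seed)
            pos, fit, _ = optimize(cfg, lambda p: -((p[0] - 42) ** 2))
            hits += pos[0] == 42
        assert hits >= 19

    def test_constant_fitness_flat_history(self):
        cfg = box(2, seed=4, n_iter=10)
        pos, fit, hist = optimize(cfg, lambda p: 1.5)
        assert fit == 1.5
        assert set(hist) == {1.5}
        assert (0 <= pos).all() and (pos <= 100).all()

    def test_sphere_reaches_top_percentile_of_grid(self):
        """2-D sphere: final best within the top 1% of all 101^2 values."""
        grid = np.array([
            -(x * x + y * y) for x in range(101) for y in range(101)
        ])
        cutoff = np.quantile(grid, 0.99)
        success = 0
        for seed in range(20):
            cfg = box(2, 0, 100, pop_size=20, n_iter=100, seed=seed)
            _, fit, _ = optimize(cfg, lambda p: -(p[0] ** 2 + p[1] ** 2))
            success += fit >= cutoff
        assert success >= 18

    def test_inertial_drift_closed_form(self):
        """ef1=ef2=0, w constant 1: position advances by the initial velocity."""
        cfg = box(1, 0, 100, w_s=1.0, w_e=1.0, ef1=0.0, ef2=0.0, seed=0,
                  velocity_clamp_frac=1.0)
        fn = lambda p: 0.0
        state = init_population(cfg, fn)
        state.positions[:] = 10.0
        state.velocities[:] = 3.0
        rng = np.random.default_rng(0)
        for k in range(1, 4):
            step(state, cfg, fn, rng)
            assert (state.positions == 10.0 + 3.0 * k).all()


class TestMemoization:
    def test_eval_count_bounded_by_unique_positions(self):
        memo = MemoizedFitness(lambda p: float(p[0]))
        for _ in range(3):
            for v in ([1.0], [2.0], [1.0]):
                memo(np.array(v))
        assert memo.n_evaluations == 2


class TestArchitectureSearch:
    @pytest.fixture()
    def tiny_task(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1, 2], 30)
        X = rng.normal(0, 1, (90, 2)) + np.array([[0, 0], [4, 0], [0, 4]])[y]
        return X[:60], y[:60], X[60:], y[60:]

    def test_single_point_space_returns_it(self, tiny_task):
        Xt, yt, Xv, yv = tiny_task
        cfg = BBOAConfig(dims=2, lower=[1, 7], upper=[1.4, 7.4], pop_size=2,
                         n_iter=1, seed=0)
        specs, _ = search_architecture(Xt, yt, Xv, yv, families=("dnn",),
                                       l_max=1, fit_epochs=5, cfg=cfg, lr=1e-3)
        assert specs["dnn"].n_hidden_layers == 1
        assert specs["dnn"].neurons == (7,)

    def test_simple_task_prefers_shallow_nets(self, tiny_task):
        """Linearly separable blobs need no depth: median answer is shallow."""
        Xt, yt, Xv, yv = tiny_task
        depths = []
        for seed in range(3):
            cfg = BBOAConfig(dims=4, lower=[1] * 4, upper=[3, 30, 30, 30],
                             pop_size=4, n_iter=3, seed=seed)
            specs, _ = search_architecture(
                Xt, yt, Xv, yv, families=("dnn",), l_max=3, fit_epochs=30,
                cfg=cfg, seed=seed, lr=1e-2,
            )
            depths.append(specs["dnn"].n_hidden_layers)
        assert np.median(depths) <= 2

    def test_empty_validation_rejected(self, tiny_task):
        Xt, yt, _, _ = tiny_task
        with pytest.raises(ValueError, match="validation"):
            search_architecture(Xt, yt, Xt[:0], yt[:0], families=("dnn",))

    def test_decode_truncates_unused_slots(self):
        base = learners.LearnerSpec(family="dnn", n_hidden_layers=1, neurons=(10,))
        spec = decode_position(np.array([2.0, 8.0, 4.0, 99.0]), "dnn", base)
        assert spec.n_hidden_layers == 2 and spec.neurons == (8, 4)
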