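"""Unit and property tests for the continuous optimizers."""

import math

import numpy as np
import pytest

from ddtpso.optimizers import (
    ConfigurationError,
    OptimizerConfig,
    Strategy,
    StrategyState,
    choose_strategy,
    dto_update,
    inertia_weight,
    init_population,
    optimize,
    pso_update,
)
from ddtpso.synthetic import benchmark_objective


def sphere(x):
    return float(np.sum(np.square(x)))


class TestInitPopulation:
    def test_positions_within_bounds(self):
        config = OptimizerConfig(bounds=(-1.0, 1.0), seed=1)
        rng = np.random.default_rng(config.seed)
        pop = init_population(config, 3, sphere, rng)
        assert pop.positions.shape == (10, 3)
        assert np.all(pop.positions >= -1.0) and np.all(pop.positions <= 1.0)
        assert np.all(pop.velocities == 0.0)

    def test_seeded_determinism(self):
        config = OptimizerConfig(bounds=(-1.0, 1.0), seed=1)
        pops = [
            init_population(config, 3, sphere, np.random.default_rng(1))
            for _ in range(2)
        ]
        assert np.array_equal(pops[0].positions, pops[1].positions)

    def test_global_best_is_min_of_initial_evaluations(self):
        config = OptimizerConfig(bounds=(-2.0, 2.0), seed=5)
        pop = init_population(config, 4, sphere, np.random.default_rng(5))
        direct = min(sphere(p) for p in pop.positions)
        assert pop.gbest_fitness == pytest.approx(direct)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            OptimizerConfig(n_agents=1)
        with pytest.raises(ConfigurationError):
            OptimizerConfig(bounds=(0.0, math.inf)).resolve_bounds(2)
        with pytest.raises(ConfigurationError):
            OptimizerConfig(exploration_fraction=0.0)


class TestPsoUpdate:
    def test_inertia_schedule_endpoints(self):
        config = OptimizerConfig()
        assert inertia_weight(0, config) == pytest.approx(0.9)
        assert inertia_weight(config.n_iterations, config) == pytest.approx(0.6)

    def test_agent_at_both_bests_with_zero_velocity_stays(self):
        config = OptimizerConfig(n_agents=2, bounds=(-5.0, 5.0), seed=0)
        pop = init_population(config, 2, sphere, np.random.default_rng(0))
        # park agent 0 exactly at its pbest == gbest with zero velocity
        pop.positions[0] = pop.gbest_position
        pop.pbest_positions[0] = pop.gbest_position
        pop.velocities[0] = 0.0
        before = pop.positions[0].copy()
        pso_update(pop, config, np.random.default_rng(1))
        assert np.allclose(pop.positions[0], before)

    def test_hand_evaluated_update_rule(self):
        # w=0, c1=0, c2=1, r2 forced to 1: x_new = x + (gbest - x) = gbest
        config = OptimizerConfig(
            n_agents=2, inertia_max=0.0, inertia_min=0.0, c1=0.0, c2=1.0,
            bounds=(-5.0, 5.0), seed=0,
        )
        pop = init_population(config, 1, sphere, np.random.default_rng(0))
        pop.positions[:] = 2.0
        pop.velocities[:] = 0.0
        pop.gbest_position = np.array([0.0])

        class OnesRng:
            def random(self, shape):
                return np.ones(shape)

        pso_update(pop, config, OnesRng())
        assert pop.positions[0, 0] == pytest.approx(0.0)


class TestDtoUpdate:
    def test_flying_hand_evaluated(self):
        # K3=K4=0, K5=1, r2=1: v = gbest - x, x_new = x + v = gbest
        config = OptimizerConfig(n_agents=2, exploration_fraction=1.0, bounds=(-5.0, 5.0))
        pop = init_population(config, 1, sphere, np.random.default_rng(3))
        pop.positions[:] = 3.0
        pop.fitness[:] = 9.0
        pop.velocities[:] = 0.0
        pop.gbest_position = np.array([1.0])

        class FixedRng:
            def random(self, shape):
                if shape == (2, 5):  # u columns: K1,K2,K3,K4,K5
                    return np.tile([0.0, 0.0, 0.0, 0.0, 1.0], (2, 1))
                return np.ones(shape)

        dto_update(pop, config, FixedRng())
        assert np.allclose(pop.positions, 1.0)

    def test_swimming_at_leader_with_zero_k1_stays(self):
        config = OptimizerConfig(n_agents=4, exploration_fraction=0.5, bounds=(-5.0, 5.0))
        pop = init_population(config, 2, sphere, np.random.default_rng(4))
        leader = int(np.argmin(pop.fitness))
        x_best = pop.positions[leader].copy()

        class ZeroK1Rng:
            def random(self, shape):
                if shape == (4, 5):
                    out = np.random.default_rng(0).random(shape)
                    out[:, 0] = 0.0  # forces K1 = 0
                    return out
                return np.random.default_rng(1).random(shape)

        dto_update(pop, config, ZeroK1Rng())
        assert np.allclose(pop.positions[leader], x_best)

    def test_global_best_never_degrades(self):
        config = OptimizerConfig(bounds=(-5.0, 5.0), seed=9)
        rng = np.random.default_rng(9)
        pop = init_population(config, 3, sphere, rng)
        for _ in range(20):
            before = pop.gbest_fitness
            dto_update(pop, config, rng)
            assert pop.gbest_fitness <= before


class TestChooseStrategy:
    def test_initial_call_returns_dto(self):
        state = StrategyState()
        assert choose_strategy(state, [], OptimizerConfig()) is Strategy.DTO

    def test_improvement_resets_stagnation(self):
        config = OptimizerConfig(swap_patience=3)
        state = StrategyState(last_best=1.0, stagnation_count=2)
        chosen = choose_strategy(state, [0.5], config)
        assert chosen is Strategy.DTO
        assert state.stagnation_count == 0

    def test_stagnation_triggers_swap_and_reset(self):
        config = OptimizerConfig(swap_patience=3)
        state = StrategyState(last_best=1.0)
        history = [1.0]
        for _ in range(2):
            assert choose_strategy(state, history, config) is Strategy.DTO
        assert choose_strategy(state, history, config) is Strategy.PSO
        assert state.stagnation_count == 0


class TestOptimize:
    def test_sphere_convergence(self):
        fn, _, _ = benchmark_objective("sphere", 5)
        result = optimize(fn, 5, OptimizerConfig(bounds=(-5.0, 5.0), seed=42))
        assert result.best_fitness <= 1e-2

    def test_constant_objective_flat_history(self):
        result = optimize(lambda x: 1.0, 3, OptimizerConfig(bounds=(0.0, 1.0), seed=0))
        assert result.best_fitness == 1.0
        assert all(v == 1.0 for v in result.best_history)

    def test_history_non_increasing_and_right_length(self):
        fn, _, _ = benchmark_objective("rastrigin", 4)
        config = OptimizerConfig(bounds=(-5.12, 5.12), n_iterations=40, seed=3)
        result = optimize(fn, 4, config)
        h = np.array(result.best_history)
        assert h.size == 40
        assert np.all(np.diff(h) <= 0)

    def test_bit_identical_under_same_seed(self):
        fn, _, _ = benchmark_objective("rosenbrock", 3)
        config = OptimizerConfig(bounds=(-2.0, 2.0), seed=17)
        r1 = optimize(fn, 3, config)
        r2 = optimize(fn, 3, config)
        assert r1.best_history == r2.best_history
        assert np.array_equal(r1.best_position, r2.best_position)

    def test_positions_stay_in_bounds_every_iteration(self):
        violations = []

        def tracked(x):
            violations.append(bool(np.any(x < -1.0) or np.any(x > 1.0)))
            return sphere(x)

        optimize(tracked, 4, OptimizerConfig(bounds=(-1.0, 1.0), n_iterations=30, seed=2))
        assert not any(violations)

    def test_strategy_log_contains_both_on_stagnating_objective(self):
        # plateau objective: improvement impossible after the first iterations,
        # forcing the stagnation swap
        def plateau(x):
            return max(1.0, float(np.sum(np.square(x))))

        config = OptimizerConfig(bounds=(-5.0, 5.0), n_iterations=40, swap_patience=5, seed=1)
        result = optimize(plateau, 3, config)
        strategies = set(result.strategy_log)
        assert len(result.strategy_log) == 40
        assert strategies == {Strategy.DTO, Strategy.PSO}

    def test_nonfinite_objective_flagged_and_best_preserved(self):
        def sometimes_nan(x):
            return float("nan") if x[0] > 0 else sphere(x)

        result = optimize(
            sometimes_nan, 2, OptimizerConfig(bounds=(-1.0, 1.0), n_iterations=20, seed=0)
        )
        assert result.n_nonfinite > 0
        assert math.isfinite(result.best_fitness)


class TestDegenerationToPlainPso:
    def test_pinned_pso_matches_independent_transcription(self):
        """With the strategy pinned to PSO, the hybrid's trajectory equals an
        independently coded textbook PSO using the same seed discipline."""
        dim, seed = 3, 123
        config = OptimizerConfig(
            n_agents=5, n_iterations=25, bounds=(-4.0, 4.0), strategy="pso", seed=seed
        )
        result = optimize(sphere, dim, config)

        # independent transcription
        rng = np.random.default_rng(seed)
        low, high = -4.0, 4.0
        x = rng.uniform(low, high, size=(5, dim))
        v = np.zeros_like(x)
        fit = np.array([sphere(p) for p in x])
        pb, pbf = x.copy(), fit.copy()
        g = int(np.argmin(pbf))
        gb, gbf = pb[g].copy(), float(pbf[g])
        history = []
        for t in range(25):
            w = 0.9 - (0.9 - 0.6) * t / 25
            r1 = rng.random((5, dim))
            r2 = rng.random((5, dim))
            v = w * v + 2.0 * r1 * (pb - x) + 2.0 * r2 * (gb - x)
            x = np.clip(x + v, low, high)
            fit = np.array([sphere(p) for p in x])
            better = fit <= pbf  # neutral moves accepted (plateau drift)
            pb[better], pbf[better] = x[better], fit[better]
            g = int(np.argmin(pbf))
            if pbf[g] < gbf:
                gbf, gb = float(pbf[g]), pb[g].copy()
            history.append(gbf)

        assert result.best_history == pytest.approx(history, abs=0.0)
        assert result.best_fitness == pytest.approx(gbf, abs=0.0)


def test_beats_random_search_on_benchmarks():
    """Mean best fitness over seeds is strictly below uniform random sampling
    with the same evaluation budget (sphere and rastrigin, d=5)."""
    for name, bound in (("sphere", 5.0), ("rastrigin", 5.12)):
        fn, _, _ = benchmark_objective(name, 5)
        opt, rand = [], []
        for seed in range(10):
            config = OptimizerConfig(bounds=(-bound, bound), seed=seed)
            opt.append(optimize(fn, 5, config).best_fitness)
            rng = np.random.default_rng(seed)
            budget = config.n_agents * (config.n_iterations + 1)
            samples = rng.uniform(-bound, bound, size=(budget, 5))
            rand.append(min(fn(s) for s in samples))
        assert np.mean(opt) < np.mean(rand), name
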