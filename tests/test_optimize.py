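"""Operator-level and loop-level tests of the firefly/DE hybrid optimizer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fireflyfit import EFAConfig, minimize, run_efa
from fireflyfit.optimize import (
    Population,
    attraction,
    de_crossover,
    de_mutate,
    de_select,
    firefly_move,
    init_population,
    partition_population,
    weak_update,
)


def cfg(**kw):
    base = dict(np_size=6, max_iter=5, bounds=[(-5.0, 5.0)] * 2, seed=0)
    base.update(kw)
    return EFAConfig(**base)


class FixedRng:
    """Deterministic stand-in generator for hand-evaluated operator examples."""

    def __init__(self, uniform=1.0, choice=None):
        self.uniform = uniform
        self.choice_value = choice

    def random(self, shape=None):
        return self.uniform if shape is None else np.full(shape, self.uniform)

    def choice(self, seq, size=None, replace=True):
        return np.asarray(self.choice_value[:size])

    def integers(self, n):
        return 0


class TestInitPopulation:
    def test_degenerate_interval(self):
        c = cfg(bounds=[(2.5, 2.5)] * 3)
        pop = init_population(c, lambda x: 0.0, np.random.default_rng(0))
        assert np.all(pop.members == 2.5)

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_within_bounds(self, seed):
        c = cfg(bounds=[(-3.0, 7.0), (0.0, 1.0)])
        pop = init_population(c, lambda x: 0.0, np.random.default_rng(seed))
        assert np.all(pop.members >= c.bounds[:, 0])
        assert np.all(pop.members <= c.bounds[:, 1])

    def test_uniform_law_monte_carlo(self):
        c = EFAConfig(np_size=10_000, max_iter=1, bounds=[(2.0, 6.0)], seed=0)
        pop = init_population(c, lambda x: 0.0, np.random.default_rng(3))
        se = 4.0 / math.sqrt(12.0) / math.sqrt(10_000)
        assert abs(pop.members.mean() - 4.0) < 3 * se


class TestAttraction:
    def test_zero_distance(self):
        assert attraction(0.0, cfg(beta0=0.8)) == pytest.approx(0.8)

    def test_no_absorption(self):
        c = cfg(beta0=0.6, phi=0.0)
        assert attraction(100.0, c) == pytest.approx(0.6)

    def test_closed_form_value(self):
        assert attraction(1.0, cfg(beta0=1.0, phi=1.0)) == pytest.approx(
            0.36787944117, rel=1e-9
        )

    def test_monotone_nonincreasing(self):
        c = cfg(beta0=1.0, phi=2.0)
        rs = np.linspace(0, 3, 50)
        betas = [attraction(r, c) for r in rs]
        assert np.all(np.diff(betas) <= 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            attraction(-0.1, cfg())


class TestFireflyMove:
    def test_no_move_toward_dimmer_neighbour(self):
        c = cfg()
        x = np.array([1.0, 1.0])
        out = firefly_move(x, np.array([2.0, 2.0]), 1.0, 5.0, c, np.random.default_rng(0))
        assert np.array_equal(out, x)

    def test_full_attraction_lands_on_target(self):
        c = cfg(alpha=0.0, phi=0.0, beta0=1.0)
        out = firefly_move(
            np.array([1.0, -1.0]), np.array([3.0, 2.0]), 5.0, 1.0, c,
            np.random.default_rng(0),
        )
        np.testing.assert_allclose(out, [3.0, 2.0])

    def test_hand_evaluated_half_step(self):
        c = cfg(alpha=0.0, phi=0.0, beta0=0.5)
        out = firefly_move(
            np.array([0.0, 0.0]), np.array([2.0, 4.0]), 5.0, 1.0, c,
            np.random.default_rng(0),
        )
        np.testing.assert_allclose(out, [1.0, 2.0])

    def test_result_clipped_to_bounds(self):
        c = cfg(bounds=[(0.0, 1.0)] * 2, alpha=5.0)
        for seed in range(10):
            out = firefly_move(
                np.array([0.5, 0.5]), np.array([1.0, 1.0]), 5.0, 1.0, c,
                np.random.default_rng(seed),
            )
            assert np.all(out >= 0.0) and np.all(out <= 1.0)


class TestPartition:
    def test_forced_example(self):
        pop = Population(members=np.zeros((4, 1)), fitness=np.array([3.0, 1.0, 2.0, 4.0]))
        pot, weak = partition_population(pop, cfg(np_size=4, potential_fraction=0.5))
        assert set(pop.fitness[pot]) == {1.0, 2.0}
        assert set(pop.fitness[weak]) == {3.0, 4.0}

    def test_stable_tie_break(self):
        pop = Population(members=np.zeros((4, 1)), fitness=np.ones(4))
        pot, _ = partition_population(pop, cfg(np_size=4, potential_fraction=0.5))
        assert list(pot) == [0, 1]

    def test_partition_is_a_partition(self):
        rng = np.random.default_rng(0)
        for np_size in (4, 5, 9):
            pop = Population(members=np.zeros((np_size, 1)), fitness=rng.random(np_size))
            pot, weak = partition_population(pop, cfg(np_size=np_size))
            combined = sorted(list(pot) + list(weak))
            assert combined == list(range(np_size))


class TestWeakUpdate:
    def test_zero_width_jumps_to_best(self):
        c = cfg(weak_width=0.0)
        x_min = np.array([1.0, -2.0])
        np.testing.assert_array_equal(
            weak_update(x_min, c, np.random.default_rng(0)), x_min
        )

    def test_stays_in_bounds(self):
        c = cfg(bounds=[(0.0, 1.0)] * 2, weak_width=5.0)
        for seed in range(10):
            out = weak_update(np.array([0.9, 0.1]), c, np.random.default_rng(seed))
            assert np.all(out >= 0.0) and np.all(out <= 1.0)

    def test_symmetric_about_best(self):
        c = cfg(bounds=[(-100.0, 100.0)], weak_width=0.1)
        rng = np.random.default_rng(0)
        draws = np.array([weak_update(np.array([3.0]), c, rng)[0] for _ in range(4000)])
        # mean of x_min + (C3 - 0.5) w (UB - LB); se = w*(UB-LB)/sqrt(12)/sqrt(n)
        se = 0.1 * 200.0 / math.sqrt(12.0) / math.sqrt(4000)
        assert abs(draws.mean() - 3.0) < 3 * se


class TestDEOperators:
    def test_identical_donors_leave_base_unchanged(self):
        pot = np.array([[1.0, 1.0], [2.0, 2.0], [2.0, 2.0], [5.0, 5.0]])
        v = de_mutate(pot, 0, cfg(mr=1.0), FixedRng(uniform=1.0, choice=[1, 2]))
        np.testing.assert_array_equal(v, pot[0])

    def test_zero_mutation_rate(self):
        pot = np.random.default_rng(0).uniform(-1, 1, (5, 3))
        v = de_mutate(pot, 2, cfg(bounds=[(-5.0, 5.0)] * 3, mr=0.0),
                      np.random.default_rng(1))
        np.testing.assert_array_equal(v, pot[2])

    def test_hand_evaluated_mutation(self):
        pot = np.array([[1.0, 1.0], [3.0, 5.0], [1.0, 1.0], [0.0, 0.0]])
        v = de_mutate(pot, 0, cfg(mr=1.0), FixedRng(uniform=1.0, choice=[1, 2]))
        np.testing.assert_allclose(v, [3.0, 5.0])

    def test_mutation_needs_four_members(self):
        with pytest.raises(ValueError):
            de_mutate(np.zeros((3, 2)), 0, cfg(), np.random.default_rng(0))

    def test_crossover_full_rate(self):
        x = np.zeros(4)
        v = np.arange(4.0)
        off = de_crossover(x, v, cfg(bounds=[(-5.0, 5.0)] * 4, cr=1.0),
                           np.random.default_rng(0))
        np.testing.assert_array_equal(off, v)

    def test_crossover_zero_rate_keeps_forced_index_only(self):
        x = np.zeros(4)
        v = np.ones(4)
        off = de_crossover(x, v, cfg(bounds=[(-5.0, 5.0)] * 4, cr=0.0),
                           FixedRng(uniform=1.0))
        assert off[0] == 1.0 and np.all(off[1:] == 0.0)

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=25, deadline=None)
    def test_crossover_components_come_from_parents(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-1, 1, 5)
        v = rng.uniform(-1, 1, 5)
        off = de_crossover(x, v, cfg(bounds=[(-5.0, 5.0)] * 5, cr=0.5), rng)
        for d in range(5):
            assert off[d] in (x[d], v[d])

    def test_selection_greedy_and_failure_safe(self):
        x = np.array([1.0])
        better, j = de_select(x, 5.0, np.array([2.0]), lambda v: 1.0)
        assert better[0] == 2.0 and j == 1.0
        parent, j = de_select(x, 5.0, np.array([2.0]), lambda v: np.inf)
        assert parent[0] == 1.0 and j == 5.0
        parent, j = de_select(x, 5.0, np.array([2.0]), lambda v: 5.0)  # tie
        assert parent[0] == 1.0


class TestMinimize:
    def test_sphere_convergence(self, sphere_objective):
        c = EFAConfig(np_size=20, max_iter=100, bounds=[(-5.0, 5.0)] * 2, seed=0)
        res = minimize(sphere_objective, c)
        assert res.best_fitness < 1e-4

    def test_plain_fa_converges_and_hybrid_wins_on_median(self, sphere_objective):
        efa_finals, fa_finals = [], []
        for seed in range(20):
            c = EFAConfig(np_size=15, max_iter=60, bounds=[(-5.0, 5.0)] * 2, seed=seed)
            efa_finals.append(minimize(sphere_objective, c).best_fitness)
            fa_finals.append(minimize(sphere_objective, c, hybrid=False).best_fitness)
        assert np.median(fa_finals) < 1e-2
        assert np.median(efa_finals) <= np.median(fa_finals)

    @pytest.mark.parametrize("hybrid", [True, False])
    def test_trace_non_increasing_and_matches_best(self, sphere_objective, hybrid):
        c = EFAConfig(np_size=8, max_iter=30, bounds=[(-5.0, 5.0)] * 3, seed=11)
        res = minimize(sphere_objective, c, hybrid=hybrid)
        assert np.all(np.diff(res.trace) <= 0)
        assert res.best_fitness == res.trace[-1]

    def test_seeded_determinism(self, sphere_objective):
        c = EFAConfig(np_size=10, max_iter=20, bounds=[(-2.0, 2.0)] * 2, seed=5)
        a = minimize(sphere_objective, c)
        b = minimize(sphere_objective, c)
        assert np.array_equal(a.best_params, b.best_params)
        assert np.array_equal(a.trace, b.trace)
        assert a.evaluations == b.evaluations

    def test_budget_accounting(self):
        calls = [0]

        def counting(x):
            calls[0] += 1
            return float(np.sum(np.asarray(x) ** 2))

        c = EFAConfig(np_size=8, max_iter=10, bounds=[(-1.0, 1.0)] * 2, seed=2)
        res = minimize(counting, c)
        assert res.evaluations == calls[0]

    def test_early_stop_on_threshold(self, sphere_objective):
        c = EFAConfig(
            np_size=20, max_iter=500, bounds=[(-5.0, 5.0)] * 2, seed=0,
            fitness_threshold=1e-3,
        )
        res = minimize(sphere_objective, c)
        assert res.best_fitness <= 1e-3
        assert res.iterations < 500


class TestRunEfaAgainstIndependentOptimizer:
    def test_single_parameter_recovery_matches_scipy_de(
        self, arginine, arginine_noiseless
    ):
        """EFA and an off-the-shelf differential-evolution solver agree on
        the one-parameter uptake-rate estimate from noiseless data."""
        from scipy.optimize import differential_evolution

        spec, truth = arginine
        free = np.array([spec.param_index("k1")])
        c = EFAConfig(np_size=12, max_iter=25, bounds=[(1.0, 500.0)], seed=4,
                      fitness_threshold=1e-10)
        res = run_efa(spec, arginine_noiseless, c, free=free, template=truth)

        from fireflyfit import Objective

        obj = Objective(spec, arginine_noiseless, free=free, template=truth)
        ref = differential_evolution(
            lambda x: obj(x), [(1.0, 500.0)], seed=1, tol=1e-12, maxiter=60,
            polish=True,
        )
        assert res.best_params[0] == pytest.approx(ref.x[0], rel=1e-3)
        assert res.best_params[0] == pytest.approx(truth[0], rel=1e-3)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"np_size": 3},
            {"mr": 1.5},
            {"cr": -0.1},
            {"potential_fraction": 1.0},
            {"alpha": -1.0},
            {"bounds": [(1.0, 0.0)]},
            {"bounds": [(0.0, np.inf)]},
            {"eval_mode": "never"},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            cfg(**kw)
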