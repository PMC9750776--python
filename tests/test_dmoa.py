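"""Dwarf mongoose optimizer: component formulas and run-level contracts."""

import numpy as np
import pytest

from mongoosenet import (
    DwarfMongooseOptimizer,
    alpha_probabilities,
    average_sleeping_mound,
    control_factor,
    fitness_mse,
    movement_vector,
    sleeping_mound,
)
from mongoosenet.dmoa import (
    MongoosePopulation,
    alpha_phase_update,
    scout_phase_update,
    write_trace_csv,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestFitnessMSE:
    def test_perfect_fit_is_zero(self):
        assert fitness_mse([1.0, 0.0, 1.0], [1, 0, 1]) == 0.0

    def test_hand_examples(self):
        assert fitness_mse([0.0, 1.0], [1, 0]) == 1.0
        assert fitness_mse([0.5], [1]) == 0.25

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            fitness_mse([0.1, 0.2], [1])


class TestAlphaProbabilities:
    def test_direct_normalization(self):
        np.testing.assert_allclose(alpha_probabilities([1, 1, 2]), [0.25, 0.25, 0.5])

    def test_constant_fitness_is_uniform(self):
        np.testing.assert_allclose(alpha_probabilities([3.0] * 5), [0.2] * 5)

    def test_single_member(self):
        np.testing.assert_allclose(alpha_probabilities([0.7]), [1.0])

    def test_all_zero_degenerates_to_uniform_with_warning(self):
        with pytest.warns(UserWarning):
            np.testing.assert_allclose(alpha_probabilities([0.0, 0.0]), [0.5, 0.5])

    def test_inverted_weighting_prefers_better_solutions(self):
        p = alpha_probabilities([0.1, 0.9], weighting="inverted")
        assert p[0] > p[1]


class TestSleepingMound:
    def test_divide_by_max_abs_difference(self):
        np.testing.assert_allclose(
            sleeping_mound([0, 0, 0], [1, 2, 4]), [0.25, 0.5, 1.0]
        )

    def test_symmetric_differences(self):
        np.testing.assert_allclose(sleeping_mound([2, 0], [0, 2]), [-1.0, 1.0])

    def test_all_zero_differences_give_zero_vector(self):
        np.testing.assert_array_equal(sleeping_mound([1, 2], [1, 2]), [0.0, 0.0])

    def test_bounded(self, rng):
        m = sleeping_mound(rng.normal(size=10), rng.normal(size=10))
        assert np.abs(m).max() <= 1.0

    def test_average(self):
        assert average_sleeping_mound([0.25, 0.5, 1.0]) == pytest.approx(7 / 12)
        assert average_sleeping_mound([0.0, 0.0]) == 0.0
        assert average_sleeping_mound([0.3]) == pytest.approx(0.3)

    def test_empty_average_errors(self):
        with pytest.raises(ValueError):
            average_sleeping_mound([])


class TestControlFactor:
    def test_endpoints_and_midpoint(self):
        assert control_factor(0, 100) == 1.0
        assert control_factor(100, 100) == 0.0
        assert control_factor(50, 100) == pytest.approx(0.5)

    def test_monotone_decay(self):
        vals = [control_factor(u, 200) for u in range(0, 201, 10)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestMovementVector:
    def test_single_mongoose_unit_mound(self):
        s = np.full((1, 4), 3.7)
        np.testing.assert_allclose(movement_vector(s, [1.0]), np.ones(4))

    def test_zero_mounds_give_zero_vector(self, rng):
        s = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(movement_vector(s, np.zeros(5)), np.zeros(3))

    def test_zero_component_contributes_nothing(self):
        s = np.array([[0.0, 2.0], [1.0, 1.0]])
        np.testing.assert_allclose(movement_vector(s, [0.5, 0.25]), [0.25, 0.75])


def make_population(rng, t=6, dim=3, lo=-5.0, hi=5.0, fn=sphere):
    sols = rng.uniform(lo, hi, (t, dim))
    pop = MongoosePopulation(
        solutions=sols,
        fitness=np.array([fn(s) for s in sols]),
        best_solution=sols[0].copy(),
        best_fitness=np.inf,
        lower=np.full(dim, lo),
        upper=np.full(dim, hi),
        max_iterations=10,
    )
    pop._refresh_best()
    return pop


class TestPhases:
    def test_zero_peep_is_null_move(self, rng):
        pop = make_population(rng)
        before = pop.solutions.copy()
        alpha_phase_update(pop, sphere, np.random.default_rng(0), peep=0.0)
        np.testing.assert_array_equal(pop.solutions, before)

    def test_alpha_accepts_only_improvements(self, rng):
        pop = make_population(rng)
        before = pop.fitness.copy()
        alpha_phase_update(pop, sphere, np.random.default_rng(1))
        assert (pop.fitness <= before).all()

    def test_scout_no_movement_at_final_iteration(self, rng):
        pop = make_population(rng)
        pop.iteration = pop.max_iterations  # D == 0
        pop.mounds = np.full(pop.size, 0.5)
        pop.omega = 0.5
        before = pop.solutions.copy()
        scout_phase_update(pop, sphere, np.random.default_rng(2), omega_prev=0.0)
        np.testing.assert_array_equal(pop.solutions, before)

    def test_phase_replay_is_deterministic(self, rng):
        pops = []
        for _ in range(2):
            pop = make_population(np.random.default_rng(7))
            alpha_phase_update(pop, sphere, np.random.default_rng(3))
            pop.mounds = np.full(pop.size, 0.1)
            pop.omega = 0.1
            pop.iteration = 2
            scout_phase_update(pop, sphere, np.random.default_rng(4), omega_prev=0.0)
            pops.append(pop.solutions.copy())
        np.testing.assert_array_equal(pops[0], pops[1])

    def test_fitness_error_reports_solution_index(self, rng):
        pop = make_population(rng)

        def bad(_x):
            raise FloatingPointError("boom")

        with pytest.raises(RuntimeError, match="solution 0"):
            alpha_phase_update(pop, bad, np.random.default_rng(0))


class TestOptimize:
    def test_converges_on_sphere(self):
        opt = DwarfMongooseOptimizer(n_mongooses=20, max_iter=80, seed=5)
        res = opt.optimize(sphere, 3, (-5, 5))
        assert res.best_fitness < 1e-2

    def test_trace_non_increasing(self):
        opt = DwarfMongooseOptimizer(n_mongooses=10, max_iter=40, seed=9)
        res = opt.optimize(sphere, 4, (-5, 5))
        trace = res.trace()
        assert (np.diff(trace) <= 0).all()

    def test_zero_iterations_returns_best_of_initial_population(self):
        opt = DwarfMongooseOptimizer(n_mongooses=10, max_iter=0, seed=3)
        res = opt.optimize(sphere, 3, (-5, 5))
        assert res.n_iterations == 0 and np.isfinite(res.best_fitness)

    def test_reproducible_under_seed(self):
        runs = [DwarfMongooseOptimizer(n_mongooses=8, max_iter=30, seed=11)
                .optimize(sphere, 3, (-5, 5)) for _ in range(2)]
        np.testing.assert_array_equal(runs[0].best_solution, runs[1].best_solution)
        assert runs[0].best_fitness == runs[1].best_fitness
        np.testing.assert_array_equal(runs[0].trace(), runs[1].trace())

    def test_solutions_respect_bounds(self):
        seen = []

        def tracked(x):
            seen.append(x.copy())
            return sphere(x)

        DwarfMongooseOptimizer(n_mongooses=6, max_iter=20, seed=2).optimize(
            tracked, 3, (-1, 2)
        )
        arr = np.array(seen)
        assert arr.min() >= -1.0 and arr.max() <= 2.0

    def test_stall_patience_terminates_early(self):
        # constant fitness cannot improve; run must stop at the patience limit
        opt = DwarfMongooseOptimizer(n_mongooses=5, max_iter=500, patience=10, seed=0)
        res = opt.optimize(lambda x: 1.0, 2, (-1, 1))
        assert res.n_iterations <= 11

    def test_invalid_config_errors_before_evaluation(self):
        calls = []

        def fn(x):
            calls.append(1)
            return sphere(x)

        with pytest.raises(ValueError):
            DwarfMongooseOptimizer(n_mongooses=1).optimize(fn, 3, (-1, 1))
        with pytest.raises(ValueError):
            DwarfMongooseOptimizer().optimize(fn, 3, (1, -1))
        assert not calls

    def test_trace_csv_round_trip(self, tmp_path):
        res = DwarfMongooseOptimizer(n_mongooses=5, max_iter=10, seed=1).optimize(
            sphere, 2, (-1, 1)
        )
        path = tmp_path / "trace.csv"
        write_trace_csv(res.history, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "iteration,best,mean,phase"
        assert len(lines) == len(res.history) + 1
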