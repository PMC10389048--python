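import numpy as np
import pytest

from conftest import ScriptedRNG

from beefit.colony import (
    ABCConfig,
    Bounds,
    Colony,
    FoodSource,
    employed_phase,
    greedy_select,
    init_colony,
    memorize_best,
    neighbor,
    onlooker_phase,
    run_abc,
    scout_phase,
    selection_probabilities,
)
from beefit.errors import DegenerateColonyError, InvalidInputError
from beefit.objective import fitness


def sphere(x):
    return float(np.dot(x, x))


def make_colony(positions, objective_fn, trials=None):
    sources = [
        FoodSource(position=np.asarray(p, dtype=float), objective=objective_fn(np.asarray(p)),
                   fitness=fitness(objective_fn(np.asarray(p))),
                   trial=0 if trials is None else trials[i])
        for i, p in enumerate(positions)
    ]
    best = min(sources, key=lambda s: s.objective)
    return Colony(sources=sources, best_position=best.position.copy(),
                  best_objective=best.objective)


class TestBounds:
    def test_validation(self):
        with pytest.raises(InvalidInputError):
            Bounds(lower=[1.0], upper=[0.0])
        with pytest.raises(InvalidInputError):
            Bounds(lower=[0.0, 0.0], upper=[1.0])

    def test_clip_and_contains(self):
        b = Bounds(lower=[0.0, -1.0], upper=[1.0, 1.0])
        assert np.array_equal(b.clip(np.array([2.0, -3.0])), [1.0, -1.0])
        assert b.contains(np.array([0.5, 0.0]))
        assert not b.contains(np.array([1.5, 0.0]))


class TestInitColony:
    def test_degenerate_bounds_collapse_to_point(self):
        cfg = ABCConfig(bounds=Bounds(lower=[2.0, 3.0], upper=[2.0, 3.0]), colony_size=5)
        colony, n = init_colony(sphere, cfg, np.random.default_rng(0))
        for s in colony.sources:
            assert np.array_equal(s.position, [2.0, 3.0])
        assert n == 5

    def test_positions_within_bounds_and_trials_zero(self):
        bounds = Bounds(lower=[-3.0, 0.5], upper=[4.0, 0.6])
        cfg = ABCConfig(bounds=bounds, colony_size=30)
        colony, _ = init_colony(sphere, cfg, np.random.default_rng(1))
        for s in colony.sources:
            assert bounds.contains(s.position)
            assert s.trial == 0
        assert colony.best_objective == min(s.objective for s in colony.sources)

    def test_same_seed_gives_identical_colony(self):
        cfg = ABCConfig(bounds=Bounds(lower=[-1.0] * 3, upper=[1.0] * 3), colony_size=8)
        c1, _ = init_colony(sphere, cfg, np.random.default_rng(9))
        c2, _ = init_colony(sphere, cfg, np.random.default_rng(9))
        for a, b in zip(c1.sources, c2.sources):
            assert np.array_equal(a.position, b.position)
            assert a.objective == b.objective

    def test_evaluation_failure_retries_then_raises(self):
        calls = []

        def flaky(x):
            calls.append(x)
            raise RuntimeError("boom")

        cfg = ABCConfig(bounds=Bounds(lower=[0.0], upper=[1.0]), colony_size=2,
                        init_retry_cap=3)
        with pytest.raises(RuntimeError):
            init_colony(flaky, cfg, np.random.default_rng(0))
        assert len(calls) == 4  # first draw + 3 retries


class TestNeighbor:
    def test_partner_never_self_and_within_bounds(self):
        bounds = Bounds(lower=[-2.0, -2.0], upper=[2.0, 2.0])
        cfg = ABCConfig(bounds=bounds, colony_size=3)
        colony = make_colony([[0.0, 0.0], [1.0, 1.0], [-1.5, 2.0]], sphere)
        rng = np.random.default_rng(3)
        for _ in range(10_000):
            v = neighbor(colony, 1, cfg, rng)
            assert bounds.contains(v)
            # a move away from source 1 can only mix in source 0 or 2
            # (k != i); the unchanged dimension must equal source 1's
            assert np.sum(v != colony.sources[1].position) <= 1

    def test_zero_phi_returns_source_unchanged(self):
        cfg = ABCConfig(bounds=Bounds(lower=[-5.0] * 2, upper=[5.0] * 2), colony_size=2)
        colony = make_colony([[1.0, 2.0], [3.0, 4.0]], sphere)
        v = neighbor(colony, 0, cfg, ScriptedRNG([0, 1, 0.0]))  # k=1, d=1, phi=0
        assert np.array_equal(v, [1.0, 2.0])

    def test_identical_coordinates_are_fixed_points(self):
        cfg = ABCConfig(bounds=Bounds(lower=[-5.0] * 2, upper=[5.0] * 2), colony_size=2)
        colony = make_colony([[1.0, 2.0], [1.0, 4.0]], sphere)
        # dimension 0 is shared: any phi leaves it unchanged
        v = neighbor(colony, 0, cfg, ScriptedRNG([0, 0, 0.9]))
        assert np.array_equal(v, [1.0, 2.0])

    def test_single_source_colony_rejected(self):
        cfg = ABCConfig(bounds=Bounds(lower=[0.0], upper=[1.0]), colony_size=2)
        colony = make_colony([[0.5]], sphere)
        with pytest.raises(DegenerateColonyError):
            neighbor(colony, 0, cfg, np.random.default_rng(0))


class TestGreedySelect:
    def test_better_candidate_replaces_with_zero_trial(self):
        cur = FoodSource(position=np.array([1.0]), objective=2.0, fitness=fitness(2.0), trial=5)
        out = greedy_select(cur, np.array([0.5]), 1.0)
        assert out.objective == 1.0 and out.trial == 0

    def test_worse_candidate_increments_trial(self):
        cur = FoodSource(position=np.array([1.0]), objective=1.0, fitness=fitness(1.0), trial=3)
        out = greedy_select(cur, np.array([2.0]), 2.0)
        assert out is cur and out.trial == 4 and out.objective == 1.0

    def test_exact_tie_keeps_incumbent_and_counts_failure(self):
        cur = FoodSource(position=np.array([1.0]), objective=1.0, fitness=fitness(1.0), trial=0)
        out = greedy_select(cur, np.array([-1.0]), 1.0)
        assert out is cur and out.trial == 1


class TestSelectionProbabilities:
    def test_examples(self):
        def fake(fits):
            colony = make_colony([[0.0]] * len(fits), lambda x: 0.0)
            for s, f in zip(colony.sources, fits):
                s.fitness = f
            return colony

        assert np.allclose(selection_probabilities(fake([1.0, 1.0, 2.0])), [0.25, 0.25, 0.5])
        assert np.allclose(selection_probabilities(fake([3.0, 3.0])), [0.5, 0.5])
        assert np.allclose(selection_probabilities(fake([0.7])), [1.0])

    def test_sum_to_one_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        colony = make_colony([[0.0]] * 10, lambda x: 0.0)
        fits = rng.uniform(0.01, 5.0, 10)
        for s, f in zip(colony.sources, fits):
            s.fitness = f
        p = selection_probabilities(colony)
        assert abs(p.sum() - 1.0) < 1e-12
        for s in colony.sources:
            s.fitness *= 37.5
        assert np.allclose(selection_probabilities(colony), p)

    def test_zero_total_fitness_rejected(self):
        colony = make_colony([[0.0]] * 3, lambda x: 0.0)
        for s in colony.sources:
            s.fitness = 0.0
        with pytest.raises(DegenerateColonyError):
            selection_probabilities(colony)


class TestPhases:
    bounds = Bounds(lower=[-10.0] * 2, upper=[10.0] * 2)

    def test_employed_all_worse_keeps_positions_and_bumps_trials(self):
        cfg = ABCConfig(bounds=self.bounds, colony_size=3)
        colony = make_colony([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]], sphere)
        seq = iter(range(100))

        def always_worse(x):
            return 1e6 + next(seq)  # every candidate is worse than any source

        before = [s.position.copy() for s in colony.sources]
        n = employed_phase(colony, always_worse, cfg, np.random.default_rng(0))
        assert n == 3
        for s, pos in zip(colony.sources, before):
            assert np.array_equal(s.position, pos)
            assert s.trial == 1

    def test_employed_all_better_replaces_everything(self):
        cfg = ABCConfig(bounds=self.bounds, colony_size=3)
        colony = make_colony([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]], sphere)
        seq = iter(range(100))

        def always_better(x):
            return -1.0 - next(seq) * 0.0  # below every source objective

        employed_phase(colony, always_better, cfg, np.random.default_rng(0))
        for s in colony.sources:
            assert s.trial == 0 and s.objective == -1.0

    def test_onlooker_concentrates_on_dominant_source(self):
        """A source holding ~all the fitness mass receives ~all placements."""
        cfg = ABCConfig(bounds=self.bounds, colony_size=3)
        colony = make_colony([[0.0, 0.0], [5.0, 5.0], [6.0, 6.0]], sphere)
        colony.sources[0].fitness = 1.0
        colony.sources[1].fitness = 1e-6
        colony.sources[2].fitness = 1e-6
        picks = []
        orig_positions = [s.position.copy() for s in colony.sources]

        rng = np.random.default_rng(5)
        n_placements = 10_000
        for _ in range(n_placements):
            probs = selection_probabilities(colony)
            r = float(rng.random())
            i = int(np.searchsorted(np.cumsum(probs), r, side="right"))
            picks.append(min(i, 2))
            neighbor(colony, picks[-1], cfg, rng)  # consume the same draws a placement would
        assert np.mean(np.array(picks) == 0) >= 0.99

        # and the phase itself, with candidates forced worse, leaves positions alone
        seq = iter(range(100_000))
        onlooker_phase(colony, lambda x: 1e9 + next(seq), cfg, np.random.default_rng(5))
        for s, pos in zip(colony.sources, orig_positions):
            assert np.array_equal(s.position, pos)

    def test_phases_are_deterministic_for_fixed_seed(self):
        cfg = ABCConfig(bounds=self.bounds, colony_size=6)

        def run_once():
            rng = np.random.default_rng(77)
            colony, _ = init_colony(sphere, cfg, rng)
            employed_phase(colony, sphere, cfg, rng)
            onlooker_phase(colony, sphere, cfg, rng)
            return np.array([s.position for s in colony.sources])

        assert np.array_equal(run_once(), run_once())


class TestScoutPhase:
    bounds = Bounds(lower=[-1.0] * 2, upper=[1.0] * 2)

    def test_no_source_over_limit_leaves_colony_unchanged(self):
        cfg = ABCConfig(bounds=self.bounds, colony_size=3, limit=5)
        colony = make_colony([[0.1, 0.1], [0.2, 0.2], [0.3, 0.3]], sphere, trials=[4, 0, 2])
        before = [s.position.copy() for s in colony.sources]
        assert scout_phase(colony, sphere, cfg, np.random.default_rng(0)) == 0
        for s, pos in zip(colony.sources, before):
            assert np.array_equal(s.position, pos)

    def test_source_at_limit_redrawn_within_bounds(self):
        cfg = ABCConfig(bounds=self.bounds, colony_size=3, limit=5)
        colony = make_colony([[0.1, 0.1], [0.9, 0.9], [0.3, 0.3]], sphere, trials=[0, 5, 0])
        scout_phase(colony, sphere, cfg, np.random.default_rng(0))
        s = colony.sources[1]
        assert s.trial == 0
        assert cfg.bounds.contains(s.position)
        assert not np.array_equal(s.position, [0.9, 0.9])

    def test_only_max_trial_source_replaced_per_cycle(self):
        cfg = ABCConfig(bounds=self.bounds, colony_size=3, limit=5)
        colony = make_colony([[0.1, 0.1], [0.5, 0.5], [0.9, 0.9]], sphere, trials=[0, 6, 9])
        scout_phase(colony, sphere, cfg, np.random.default_rng(0))
        assert np.array_equal(colony.sources[1].position, [0.5, 0.5])  # stays (6 < 9)
        assert colony.sources[1].trial == 6
        assert colony.sources[2].trial == 0  # redrawn

    def test_best_source_is_never_abandoned(self):
        cfg = ABCConfig(bounds=self.bounds, colony_size=3, limit=5)
        colony = make_colony([[0.0, 0.0], [0.5, 0.5], [0.9, 0.9]], sphere, trials=[50, 0, 0])
        scout_phase(colony, sphere, cfg, np.random.default_rng(0))
        assert np.array_equal(colony.sources[0].position, [0.0, 0.0])


class TestMemorizeBest:
    def test_updates_only_on_strict_improvement(self):
        colony = make_colony([[1.0], [2.0]], sphere)
        colony.best_objective = 0.5
        colony.best_position = np.array([0.7])
        memorize_best(colony)  # colony min is 1.0 > 0.5: unchanged
        assert colony.best_objective == 0.5
        colony.sources[0].objective = 0.1
        colony.sources[0].position = np.array([0.3])
        memorize_best(colony)
        assert colony.best_objective == 0.1
        assert np.array_equal(colony.best_position, [0.3])


class TestRunABC:
    bounds = Bounds(lower=[-5.0, -5.0], upper=[5.0, 5.0])

    def test_zero_cycles_returns_initial_best(self):
        cfg = ABCConfig(bounds=self.bounds, colony_size=10, max_cycles=0, seed=4)
        result = run_abc(sphere, cfg)
        assert result.n_evaluations == 10
        assert result.trace == [result.best_objective]

    def test_evaluation_count_identity(self):
        cfg = ABCConfig(bounds=self.bounds, colony_size=7, limit=3, max_cycles=25, seed=0)
        result = run_abc(sphere, cfg)
        # SN + 2*SN*cycles plus at most one scout redraw per cycle
        base = 7 + 2 * 7 * 25
        assert base <= result.n_evaluations <= base + 25

    def test_bit_identical_for_fixed_seed(self):
        cfg = ABCConfig(bounds=self.bounds, colony_size=10, limit=5, max_cycles=30, seed=123)
        r1, r2 = run_abc(sphere, cfg), run_abc(sphere, cfg)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert r1.best_objective == r2.best_objective
        assert r1.trace == r2.trace
        assert r1.n_evaluations == r2.n_evaluations

    def test_trace_monotone_and_best_within_bounds(self):
        for seed in range(5):
            cfg = ABCConfig(bounds=self.bounds, colony_size=10, limit=5,
                            max_cycles=50, seed=seed)
            r = run_abc(sphere, cfg)
            assert all(b <= a for a, b in zip(r.trace, r.trace[1:]))
            assert self.bounds.contains(r.best_position)

    def test_colony_is_fixed_point_with_zero_phi_and_infinite_limit(self):
        """With phi forced to 0 every candidate equals its source; ties are
        rejected, so employed + onlooker phases change nothing."""
        cfg = ABCConfig(bounds=self.bounds, colony_size=3, limit=10**9)
        colony = make_colony([[1.0, 2.0], [3.0, -1.0], [0.5, 0.5]], sphere)
        before = [s.position.copy() for s in colony.sources]
        # employed: per source (k, d, phi); onlooker: (roulette, k, d, phi)
        script = [0, 0, 0.0] * 3 + [0.0, 0, 0, 0.0] * 3
        employed_phase(colony, sphere, cfg, ScriptedRNG(script[:9]))
        onlooker_phase(colony, sphere, cfg, ScriptedRNG(script[9:]))
        for s, pos in zip(colony.sources, before):
            assert np.array_equal(s.position, pos)
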