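"""Cooperative mechanisms: hybridization, reorganization, transfer, elite
local search, stagnation restart, and the success-rate memory."""

import numpy as np
import pytest

from coopfs.cooperation import (
    ControlState,
    CoopConfig,
    cooperative_transfer,
    elite_local_search,
    greedy_select,
    hybridize,
    reorganize_worst,
    stagnation_restart,
    update_success_memory,
)
from coopfs.population import EvalOutcome, Population


class QuadraticProblem:
    """f(x) = ||x - centre||^2 on a box; the cooperative ops' test target."""

    def __init__(self, n=3, centre=0.0, lo=-5.0, hi=5.0):
        self.lower = np.full(n, lo)
        self.upper = np.full(n, hi)
        self.centre = np.full(n, centre)
        self.n_dim = n
        self.n_evaluations = 0

    def evaluate(self, x, rng):
        self.n_evaluations += 1
        return EvalOutcome(fitness=float(np.sum((x - self.centre) ** 2)))


def make_population(problem, X, groups):
    rng = np.random.default_rng(0)
    fit = np.array([problem.evaluate(x, rng).fitness for x in X])
    return Population(
        X=X.copy(),
        fitness=fit,
        accuracy=np.full(len(X), np.nan),
        groups=[np.asarray(g) for g in groups],
        roles=["exploration", "exploitation", "balance"][: len(groups)],
    )


class ConstRng:
    """Stub generator with fixed uniform/normal outputs."""

    def __init__(self, uniform=0.5, normal=0.0):
        self.u, self.n = uniform, normal

    def random(self, n=None):
        return self.u if n is None else np.full(n, self.u)

    def normal(self, loc, scale, size=None):
        shape = np.shape(scale) if size is None else size
        return np.full(shape, self.n) if shape else self.n

    def integers(self, *a, **k):
        return 0


class TestGreedySelect:
    def test_strict_improvement_accepts(self):
        assert greedy_select(0.3, 0.2)

    def test_equal_fitness_keeps_parent(self):
        assert not greedy_select(0.2, 0.2)

    def test_worse_trial_rejected(self):
        assert not greedy_select(0.2, 0.3)


class TestSuccessMemory:
    def test_no_activity_gives_near_zero_batch(self):
        c = ControlState(n_groups=2)
        batch = update_success_memory(c)
        assert batch[0] == pytest.approx(0.0, abs=1e-6)

    def test_balanced_counts_give_half(self):
        c = ControlState(n_groups=1)
        for _ in range(4):
            c.record(0, True)
            c.record(0, False)
        assert update_success_memory(c)[0] == pytest.approx(0.5, rel=1e-6)

    def test_ema_arithmetic(self):
        c = ControlState(n_groups=1)
        c.record(0, True)  # batch ratio ~ 1
        update_success_memory(c)
        assert c.memory[0] == pytest.approx(0.65, rel=1e-6)

    def test_counters_reset_after_update(self):
        c = ControlState(n_groups=1)
        c.record(0, True)
        update_success_memory(c)
        assert c.successes[0] == 0 and c.failures[0] == 0

    def test_counter_conservation(self):
        c = ControlState(n_groups=3)
        draws = np.random.default_rng(5).random(60) < 0.4
        for i, ok in enumerate(draws):
            c.record(i % 3, bool(ok))
        assert (c.successes + c.failures).sum() == 60


class TestHybridize:
    def test_endpoint_r_one_reproduces_first_parent(self):
        problem = QuadraticProblem()
        X = np.arange(9.0).reshape(3, 3)
        pop = make_population(problem, X, [[0], [1], [2]])
        captured = []
        orig = problem.evaluate

        def spy(x, rng):
            captured.append(x.copy())
            return orig(x, rng)

        problem.evaluate = spy
        hybridize(pop, problem, ConstRng(uniform=1.0), n_pairs=1)
        np.testing.assert_allclose(captured[0], X[0])

    def test_equal_fitness_hybrid_not_accepted(self):
        problem = QuadraticProblem()
        X = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        pop = make_population(problem, X, [[0], [1], [2]])
        # all parents and any blend along these axes have fitness >= 1;
        # force the hybrid to score exactly the better parent's fitness
        problem.evaluate = lambda x, rng: EvalOutcome(fitness=1.0)
        before = pop.X.copy()
        hybridize(pop, problem, np.random.default_rng(0), n_pairs=3)
        np.testing.assert_array_equal(pop.X, before)

    def test_convex_fitness_parents_straddling_optimum(self):
        # 1-D convex objective: some blend of straddling parents must win,
        # verified independently by a grid search over the blend weight
        problem = QuadraticProblem(n=1, centre=0.0)
        X = np.array([[-2.0], [1.5], [4.0]])
        pop = make_population(problem, X, [[0], [1], [2]])
        grid = np.linspace(0, 1, 101)
        blends = grid * X[0, 0] + (1 - grid) * X[1, 0]
        assert (blends**2 < min(4.0, 2.25)).any()
        improved = False
        for seed in range(10):
            pop2 = make_population(problem, X, [[0], [1], [2]])
            hybridize(pop2, problem, np.random.default_rng(seed), n_pairs=1)
            if pop2.fitness.min() < pop.fitness.min() or not np.array_equal(pop2.X, pop.X):
                improved = True
        assert improved


class TestReorganize:
    def test_midpoint_draw_reproduces_seed(self):
        problem = QuadraticProblem()
        X = np.array([[0.0, 0, 0], [1, 1, 1], [3, 3, 3], [4, 4, 4]])
        pop = make_population(problem, X, [[0], [1], [2, 3]])
        reorganize_worst(pop, problem, ConstRng(uniform=0.5))
        # group [2, 3] has the highest mean fitness; u = 0.5 -> zero offset
        np.testing.assert_allclose(pop.X[3], X[2])

    def test_offsets_bounded_by_eighth_of_box(self):
        problem = QuadraticProblem(n=4, lo=-8.0, hi=8.0)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(9, 4))
        pop = make_population(problem, X, [[0, 1, 2], [3, 4, 5], [6, 7, 8]])
        means = [pop.group_mean_fitness(g) for g in range(3)]
        worst = int(np.argmax(means))
        seed_row = pop.X[pop.group_order(worst)[0]].copy()
        reorganize_worst(pop, problem, rng)
        for idx in pop.groups[worst]:
            assert np.all(np.abs(pop.X[idx] - seed_row) <= 0.125 * 16.0 + 1e-12)

    def test_targets_argmax_mean_fitness_group(self):
        problem = QuadraticProblem()
        X = np.vstack([np.zeros((2, 3)), np.ones((2, 3)), np.full((2, 3), 4.0)])
        pop = make_population(problem, X, [[0, 1], [2, 3], [4, 5]])
        before = pop.X.copy()
        reorganize_worst(pop, problem, np.random.default_rng(0))
        assert np.array_equal(pop.X[:4], before[:4])  # healthier groups untouched
        assert not np.array_equal(pop.X[4:], before[4:])


class TestTransfer:
    def test_zero_noise_blend_weights(self):
        problem = QuadraticProblem()
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        pop = make_population(problem, X, [[0, 1], [2, 3], [4, 5]])
        donors = [pop.X[pop.group_order(g)[0]].copy() for g in range(3)]
        worsts = [pop.X[pop.group_order(g)[-1]].copy() for g in range(3)]
        worst_ids = [int(pop.group_order(g)[-1]) for g in range(3)]
        cooperative_transfer(pop, problem, ConstRng(normal=0.0), sigma=0.0)
        for recv in range(3):
            expected = 0.7 * donors[(recv - 1) % 3] + 0.3 * worsts[recv]
            np.testing.assert_allclose(pop.X[worst_ids[recv]], expected, rtol=1e-12)

    def test_identical_donor_and_receiver_unchanged(self):
        problem = QuadraticProblem()
        X = np.tile(np.array([1.0, 2.0, 3.0]), (6, 1))
        pop = make_population(problem, X, [[0, 1], [2, 3], [4, 5]])
        cooperative_transfer(pop, problem, ConstRng(normal=0.0), sigma=0.0)
        np.testing.assert_allclose(pop.X, X)


class TestEliteLocalSearch:
    def test_zero_radius_probe_never_replaces(self):
        problem = QuadraticProblem()
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 3))
        pop = make_population(problem, X, [[0, 1], [2, 3], [4]])
        before = pop.X.copy()
        events = []
        elite_local_search(pop, problem, rng, radius=0.0, events=events)
        np.testing.assert_array_equal(pop.X, before)
        assert events == []

    def test_worse_probe_keeps_parent(self):
        problem = QuadraticProblem()
        X = np.zeros((5, 3))  # parents at the optimum: any probe is worse
        pop = make_population(problem, X, [[0, 1], [2, 3], [4]])
        elite_local_search(pop, problem, np.random.default_rng(0), radius=0.5)
        np.testing.assert_array_equal(pop.X, X)

    def test_acceptance_rate_matches_monte_carlo_oracle(self):
        # 1-D quadratic, parent off-optimum: acceptance frequency of the
        # Gaussian probe should match a direct Monte-Carlo estimate of
        # P(|x0 + xi| < |x0|)
        x0, radius = 1.0, 0.05  # probe sd = radius * (hi - lo) = 0.5
        problem = QuadraticProblem(n=1)
        rng = np.random.default_rng(9)
        n_trials = 3000
        accepted = 0
        for _ in range(n_trials):
            pop = Population(
                X=np.array([[x0]]),
                fitness=np.array([x0**2]),
                accuracy=np.array([np.nan]),
                groups=[np.array([0])],
                roles=["exploration"],
            )
            elite_local_search(pop, problem, rng, radius=radius)
            accepted += pop.X[0, 0] != x0
        xi = np.random.default_rng(10).normal(0, radius * 10.0, 200_000)
        p_oracle = np.mean((x0 + xi) ** 2 < x0**2)
        se = np.sqrt(p_oracle * (1 - p_oracle) / n_trials)
        assert abs(accepted / n_trials - p_oracle) < 4 * se


class TestStagnationRestart:
    def _pop(self, problem, n=30):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(n, 3))
        groups = [np.arange(0, 10), np.arange(10, 20), np.arange(20, n)]
        return make_population(problem, X, groups)

    def test_exact_count_and_best_survival(self):
        problem = QuadraticProblem()
        pop = self._pop(problem)
        control = ControlState(n_groups=3, stagnation_counter=30)
        best_before = pop.best_fitness
        best_member = int(np.argmin(pop.fitness))
        best_row = pop.X[best_member].copy()
        events = []
        stagnation_restart(
            pop, problem, control, np.random.default_rng(0),
            delta=1.0, sigma=0.05, fraction=0.2, events=events,
        )
        assert len(events) == 6  # ceil(0.2 * 30)
        assert pop.size == 30
        np.testing.assert_array_equal(pop.X[best_member], best_row)
        assert pop.best_fitness <= best_before
        assert control.stagnation_counter == 0

    def test_regeneration_centres_on_best(self):
        problem = QuadraticProblem()
        pop = self._pop(problem)
        control = ControlState(n_groups=3, stagnation_counter=30)
        worst = int(np.argmax(pop.fitness))
        stagnation_restart(
            pop, problem, control, ConstRng(normal=0.0),
            delta=0.05, sigma=0.05, fraction=0.2,
        )
        np.testing.assert_allclose(pop.X[worst], pop.best_x)


def test_coop_config_validation():
    with pytest.raises(ValueError):
        CoopConfig(hybrid_period=0)
    with pytest.raises(ValueError):
        CoopConfig(restart_fraction=0.0)
    with pytest.raises(ValueError):
        CoopConfig(hybrid_pairs=0)


def test_global_best_monotone_under_all_operations():
    problem = QuadraticProblem(n=4)
    rng = np.random.default_rng(12)
    X = rng.normal(size=(12, 4))
    pop = make_population(problem, X, [np.arange(4), np.arange(4, 8), np.arange(8, 12)])
    control = ControlState(n_groups=3, stagnation_counter=30)
    history = [pop.best_fitness]
    hybridize(pop, problem, rng, n_pairs=4)
    history.append(pop.best_fitness)
    reorganize_worst(pop, problem, rng)
    history.append(pop.best_fitness)
    cooperative_transfer(pop, problem, rng, sigma=0.05)
    history.append(pop.best_fitness)
    elite_local_search(pop, problem, rng, radius=0.05)
    history.append(pop.best_fitness)
    stagnation_restart(pop, problem, control, rng, delta=0.5, sigma=0.05, fraction=0.2)
    history.append(pop.best_fitness)
    assert np.all(np.diff(history) <= 0)
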