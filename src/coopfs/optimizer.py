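"""Main loop of the cooperative three-subpopulation optimizer, and the
public entry points for continuous minimization and wrapper feature
selection.

One iteration updates each subpopulation with its own operator, applies
greedy (strictly-better) replacement, then fires the periodic cooperative
mechanisms in a fixed order — hybridization, reorganization, elite local
search, cyclic transfer — followed by the stagnation check/restart and the
success-memory update.  Total cost is O(T_max * NP * C_fit) fitness
evaluations plus the (logged) event evaluations, where C_fit is the cost of
one candidate evaluation (a cross-validated classifier fit in feature-
selection mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import cooperation as coop
from . import operators as ops
from .cooperation import ControlState, CoopConfig
from .encoding import (
    FitnessEvaluator,
    FitnessRecord,
    FitnessWeights,
    binarize,
    decode_deterministic,
)
from .fisher import fisher_scores, select_top
from .population import EvalOutcome, Population

logger = logging.getLogger(__name__)

__all__ = [
    "OptimizerConfig",
    "RunTrace",
    "ContinuousProblem",
    "FeatureSelectionProblem",
    "FeatureSelectionResult",
    "run",
    "minimize",
    "select_features",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Full configuration of a run (all mechanism constants plus toggles).

    The ablation toggles map onto the named variants: ``use_levy`` (–LF),
    ``use_adaptive`` (–AD), ``use_cooperation`` (–CO: hybridization and
    cyclic transfer), ``use_reorganization`` (–REO), ``use_restart_local``
    (–RS: stagnation restart and elite local search), ``use_fisher_filter``
    (no-filter), and ``subpop_count`` 2/3/4 (2SP/4SP structural variants).
    """

    population_size: int = 30
    max_iterations: int = 100
    seed: int = 42
    subpop_count: int = 3

    # feature-selection search box; [-4, 4] keeps the transfer probabilities
    # in roughly [0.12, 0.88] so compact subsets are reachable
    lower_bound: float = -4.0
    upper_bound: float = 4.0

    alpha: float = 0.99
    classifier: str = "svm"
    inner_folds: int = 5
    filter_size: int = 300

    elite_pull: float = 0.7
    pbest_fraction: float = 0.2
    noise_scale: float = 0.05
    levy_exponent: float = 1.5

    coop: CoopConfig = field(default_factory=CoopConfig)

    use_levy: bool = True
    use_adaptive: bool = True
    use_cooperation: bool = True
    use_reorganization: bool = True
    use_restart_local: bool = True
    use_fisher_filter: bool = True

    deterministic_decode: bool = False
    stagnation_tol: float = 1e-12

    def __post_init__(self):
        if self.subpop_count not in (2, 3, 4):
            raise ValueError("subpop_count must be 2, 3 or 4")
        if self.population_size < 3 * self.subpop_count:
            raise ValueError(
                "population_size must be at least 3 * subpop_count "
                f"({3 * self.subpop_count})"
            )
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.lower_bound >= self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")

    def roles(self) -> list:
        base = ["exploration", "exploitation", "balance", "balance"]
        if self.subpop_count == 2:
            return ["exploration", "exploitation"]
        return base[: self.subpop_count]

    def subpop_params(self, role: str) -> ops.SubpopParams:
        return ops.SubpopParams.for_role(
            role,
            noise_scale=self.noise_scale,
            levy_exponent=self.levy_exponent,
            elite_pull=self.elite_pull,
            pbest_fraction=self.pbest_fraction,
        )


@dataclass
class RunTrace:
    """Per-iteration history of one run.

    ``best_fitness`` is non-increasing by construction.  ``success_ratio``
    holds each subpopulation's per-iteration batch success ratio R_k (the
    operator-attribution signal).  ``event_evaluations`` counts the extra
    fitness evaluations per cooperative mechanism, so the total evaluation
    budget NP * (1 + T) + events is auditable.
    """

    best_fitness: np.ndarray
    best_accuracy: np.ndarray
    success_ratio: np.ndarray  # (T, n_groups)
    events: list
    n_evaluations: int
    event_evaluations: dict
    final_x: np.ndarray
    final_fitness: float
    final_accuracy: float


class ContinuousProblem:
    """Box-constrained continuous minimization target."""

    def __init__(self, objective, lower, upper):
        self.objective = objective
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("bound shapes differ")
        self.n_dim = self.lower.size
        self.n_evaluations = 0

    def evaluate(self, x, rng) -> EvalOutcome:
        self.n_evaluations += 1
        return EvalOutcome(fitness=float(self.objective(x)))


class FeatureSelectionProblem:
    """Wrapper feature-selection target: continuous vectors are decoded to
    masks and scored by cross-validated accuracy plus a size penalty."""

    def __init__(self, evaluator: FitnessEvaluator, lower_bound, upper_bound):
        self.evaluator = evaluator
        n = evaluator.n_features
        self.lower = np.full(n, float(lower_bound))
        self.upper = np.full(n, float(upper_bound))
        self.n_dim = n
        self.n_evaluations = 0  # evaluation requests (cache hits included)

    def evaluate(self, x, rng) -> EvalOutcome:
        self.n_evaluations += 1
        record = self.evaluator.evaluate_mask(binarize(x, rng))
        return EvalOutcome(fitness=record.fitness, accuracy=record.accuracy)


def _partition(n: int, n_groups: int) -> list:
    """Contiguous index blocks of size n // n_groups; the remainder joins
    the last (balance) group."""
    base = n // n_groups
    sizes = [base] * n_groups
    sizes[-1] += n - base * n_groups
    blocks, start = [], 0
    for s in sizes:
        blocks.append(np.arange(start, start + s))
        start += s
    return blocks


def run(problem, config: OptimizerConfig) -> RunTrace:
    """Run the optimizer on ``problem`` and return the full trace.

    The problem supplies ``lower``/``upper`` bound vectors and
    ``evaluate(x, rng) -> EvalOutcome``.  All randomness flows through one
    generator seeded from ``config.seed``; identical seed and input give a
    bit-identical trace.
    """
    rng = np.random.default_rng(config.seed)
    NP = config.population_size
    T = config.max_iterations
    lower, upper = problem.lower, problem.upper
    n = problem.n_dim

    X = lower + rng.random((NP, n)) * (upper - lower)
    outcomes = [problem.evaluate(X[i], rng) for i in range(NP)]
    fitness = np.array([o.fitness for o in outcomes])
    accuracy = np.array([o.accuracy for o in outcomes])

    roles = config.roles()
    groups = _partition(NP, config.subpop_count)
    pop = Population(X=X, fitness=fitness, accuracy=accuracy, groups=groups, roles=roles)
    params = [config.subpop_params(role) for role in roles]
    control = ControlState(n_groups=len(groups))
    cfg_coop = config.coop

    best_hist = np.empty(T)
    acc_hist = np.empty(T)
    ratio_hist = np.empty((T, len(groups)))
    events: list = []
    event_evals = {
        "hybridization": 0,
        "reorganization": 0,
        "local_search": 0,
        "transfer": 0,
        "restart": 0,
    }

    for t in range(1, T + 1):
        schedule = ops.ScheduleState(
            iteration=t,
            max_iterations=T,
            local_radius_base=cfg_coop.local_radius_base,
        )
        for g, idx in enumerate(groups):
            par = params[g]
            if config.use_adaptive:
                scale = ops.adaptive_scale(par.base_scale, control.memory[g], t, T)
            else:
                scale = par.base_scale
            for local_i, member in enumerate(idx):
                # asynchronous: trials see all replacements made so far,
                # and the elite pool is refreshed per trial
                pbest_pool = pop.pbest_pool(config.pbest_fraction)
                subpop = pop.X[idx]
                if par.role == "exploration":
                    v = ops.explore_update(
                        local_i, subpop, pbest_pool, scale, par,
                        lower, upper, rng, use_levy=config.use_levy,
                    )
                elif par.role == "exploitation":
                    sub_best = subpop[int(np.argmin(pop.fitness[idx]))]
                    v = ops.exploit_update(
                        subpop[local_i], pop.best_x, sub_best, pbest_pool,
                        scale, par, lower, upper, rng,
                    )
                else:
                    v = ops.balance_update(
                        local_i, subpop, pop.best_x, pbest_pool, scale, par,
                        lower, upper, rng, use_levy=config.use_levy,
                    )
                outcome = problem.evaluate(v, rng)
                if coop.greedy_select(pop.fitness[member], outcome.fitness):
                    pop.set_member(int(member), v, outcome)
                    control.record(g, True)
                else:
                    control.record(g, False)

        if config.use_cooperation and t % cfg_coop.hybrid_period == 0:
            coop.hybridize(pop, problem, rng, cfg_coop.hybrid_pairs, t, events)
            event_evals["hybridization"] += cfg_coop.hybrid_pairs
        if config.use_reorganization and t % cfg_coop.reorg_period == 0:
            means = [pop.group_mean_fitness(g) for g in range(len(groups))]
            worst_size = groups[int(np.argmax(means))].size
            coop.reorganize_worst(pop, problem, rng, t, events)
            event_evals["reorganization"] += worst_size - 1
        if config.use_restart_local and t % cfg_coop.local_period == 0:
            coop.elite_local_search(pop, problem, rng, schedule.local_radius, t, events)
            event_evals["local_search"] += max(1, int(np.ceil(0.1 * NP)))
        if config.use_cooperation and t % cfg_coop.coop_period == 0:
            coop.cooperative_transfer(pop, problem, rng, config.noise_scale, t, events)
            event_evals["transfer"] += len(groups)

        prev_best = best_hist[t - 2] if t > 1 else np.inf
        improved = pop.best_fitness < prev_best - config.stagnation_tol
        if improved:
            control.stagnation_counter = 0
        else:
            control.stagnation_counter += 1
        if (
            config.use_restart_local
            and control.stagnation_counter >= cfg_coop.stagnation_limit
        ):
            k = max(1, int(np.ceil(cfg_coop.restart_fraction * NP)))
            coop.stagnation_restart(
                pop, problem, control, rng, schedule.restart_scale,
                config.noise_scale, cfg_coop.restart_fraction, t, events,
            )
            event_evals["restart"] += min(k, NP - 1)

        ratio_hist[t - 1] = coop.update_success_memory(control)
        best_hist[t - 1] = pop.best_fitness
        acc_hist[t - 1] = pop.best_accuracy

    return RunTrace(
        best_fitness=best_hist,
        best_accuracy=acc_hist,
        success_ratio=ratio_hist,
        events=events,
        n_evaluations=problem.n_evaluations,
        event_evaluations=event_evals,
        final_x=pop.best_x.copy(),
        final_fitness=float(pop.best_fitness),
        final_accuracy=float(pop.best_accuracy),
    )


def minimize(objective, n_dim=None, bounds=(-100.0, 100.0), config=None) -> RunTrace:
    """Minimize a continuous objective over a box.

    ``objective`` may be a plain callable (then ``n_dim`` is required and
    ``bounds`` is a (low, high) pair applied per dimension) or a
    :class:`coopfs.benchmarks.BenchmarkFunction`, which carries its own
    dimension and bounds.
    """
    config = config or OptimizerConfig()
    dim = getattr(objective, "dimension", None) or n_dim
    if dim is None:
        raise ValueError("n_dim is required for a plain callable objective")
    lo, hi = getattr(objective, "bounds", bounds)
    problem = ContinuousProblem(
        objective, np.full(dim, float(lo)), np.full(dim, float(hi))
    )
    return run(problem, config)


@dataclass
class FeatureSelectionResult:
    """Outcome of a feature-selection run: the decoded subset in original
    feature space plus the optimizer trace."""

    selected_indices: np.ndarray
    selected_names: list
    record: FitnessRecord
    trace: RunTrace
    filtered_indices: np.ndarray

    @property
    def accuracy(self) -> float:
        return self.record.accuracy

    @property
    def subset_size(self) -> int:
        return self.record.subset_size


def select_features(X, y, config: OptimizerConfig | None = None, feature_names=None) -> FeatureSelectionResult:
    """Two-stage feature selection: Fisher filter then cooperative wrapper
    search.

    The final best continuous vector is decoded through a dedicated seeded
    stream (or deterministically, coordinate > 0, when
    ``config.deterministic_decode``) and mapped back to original feature
    identifiers.
    """
    config = config or OptimizerConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("feature selection requires at least 2 classes")
    n_total = X.shape[1]

    if config.use_fisher_filter:
        table = fisher_scores(X, y)
        keep = select_top(table, min(config.filter_size, n_total))
        if config.filter_size > n_total:
            logger.warning(
                "filter size %d exceeds feature count %d; keeping all",
                config.filter_size,
                n_total,
            )
    else:
        keep = np.arange(n_total)

    weights = FitnessWeights(
        alpha=config.alpha,
        classifier_kind="gradient_boosting" if config.classifier in ("xgb", "gradient_boosting") else "svm",
        inner_folds=config.inner_folds,
    )
    evaluator = FitnessEvaluator(X[:, keep], y, weights, seed=config.seed)
    problem = FeatureSelectionProblem(evaluator, config.lower_bound, config.upper_bound)
    trace = run(problem, config)

    if config.deterministic_decode:
        mask = decode_deterministic(trace.final_x)
    else:
        decode_rng = np.random.default_rng([config.seed, 7919])
        mask = binarize(trace.final_x, decode_rng)
    record = evaluator.evaluate_mask(mask)

    selected_local = np.flatnonzero(mask)
    selected_orig = np.sort(keep[selected_local])
    if feature_names is None:
        feature_names = [f"f{i + 1}" for i in range(n_total)]
    names = [feature_names[i] for i in selected_orig]
    return FeatureSelectionResult(
        selected_indices=selected_orig,
        selected_names=names,
        record=record,
        trace=trace,
        filtered_indices=keep,
    )
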