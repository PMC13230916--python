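"""Cross-subpopulation cooperation, elite local search, restart, and the
success-rate adaptive memory.

Periodic mechanisms knit the three subpopulations together:

* hybridization — elite parents from two different groups are blended
  ``h = r x_a + (1 - r) x_b``; the hybrid replaces the worse parent only if
  strictly better than both;
* reorganization — the group with the highest mean fitness is regenerated
  around its own best member;
* cyclic transfer — each group's worst member is pulled toward the previous
  group's best along a fixed exploration -> exploitation -> balance cycle;
* elite local search — the top 10% spawn shrinking Gaussian probes accepted
  only on strict improvement;
* stagnation restart — after ``T_stag`` iterations without improvement the
  worst fraction is reseeded near the incumbent best with a floor of 0.05 on
  the perturbation scale.

Success/failure counters from greedy selection feed an exponential moving
memory of each group's success ratio, which modulates the adaptive step
scale of :func:`coopfs.operators.adaptive_scale`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .population import EvalOutcome, Population

__all__ = [
    "CoopConfig",
    "ControlState",
    "greedy_select",
    "hybridize",
    "reorganize_worst",
    "cooperative_transfer",
    "elite_local_search",
    "stagnation_restart",
    "update_success_memory",
]


@dataclass(frozen=True)
class CoopConfig:
    """Periods and sizes of the cooperative mechanisms (defaults as used
    throughout: T_hyb=5, T_reorg=12, T_local=8, rho0=0.12, T_coop=6,
    T_stag=30, restart fraction 0.2, 4 hybrid pairs per event)."""

    hybrid_period: int = 5
    reorg_period: int = 12
    local_period: int = 8
    local_radius_base: float = 0.12
    coop_period: int = 6
    stagnation_limit: int = 30
    restart_fraction: float = 0.2
    hybrid_pairs: int = 4

    def __post_init__(self):
        for name in ("hybrid_period", "reorg_period", "local_period", "coop_period"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.restart_fraction <= 1.0:
            raise ValueError("restart_fraction must lie in (0, 1]")
        if self.hybrid_pairs < 1:
            raise ValueError("hybrid_pairs must be >= 1")


@dataclass
class ControlState:
    """Per-subpopulation success bookkeeping.

    ``memory`` is an exponential moving average of the batch success ratio
    (weights 0.7 old / 0.3 new), initialized at 0.5; counters are drained at
    the end of every iteration.
    """

    n_groups: int
    epsilon: float = 1e-9
    successes: np.ndarray = field(default=None)
    failures: np.ndarray = field(default=None)
    memory: np.ndarray = field(default=None)
    stagnation_counter: int = 0

    def __post_init__(self):
        if self.successes is None:
            self.successes = np.zeros(self.n_groups, dtype=int)
        if self.failures is None:
            self.failures = np.zeros(self.n_groups, dtype=int)
        if self.memory is None:
            self.memory = np.full(self.n_groups, 0.5)

    def record(self, group: int, success: bool):
        if success:
            self.successes[group] += 1
        else:
            self.failures[group] += 1


def greedy_select(f_current: float, f_trial: float) -> bool:
    """True iff the trial strictly improves on the incumbent (Eq.-style
    strict ``<``: equal fitness keeps the parent)."""
    return f_trial < f_current


def update_success_memory(control: ControlState) -> np.ndarray:
    """Fold one iteration's counters into the moving success memory and
    reset them.  Returns the batch ratios R_k = s / (s + f + eps)."""
    s = control.successes.astype(float)
    f = control.failures.astype(float)
    batch = s / (s + f + control.epsilon)
    control.memory = 0.7 * control.memory + 0.3 * batch
    control.successes[:] = 0
    control.failures[:] = 0
    return batch


def _log(events, t, kind, group, f_before, f_after):
    if events is not None:
        events.append(
            {
                "iteration": int(t),
                "event": kind,
                "group": int(group) if group is not None else -1,
                "fitness_before": float(f_before),
                "fitness_after": float(f_after),
            }
        )


def hybridize(pop: Population, problem, rng, n_pairs: int, t=0, events=None):
    """Heterosis-style recombination of elite parents across groups.

    Forms ``n_pairs`` pairs by round-robin over the distinct group pairs;
    the k-th visit to a pair uses each group's (k+1)-th ranked member.  The
    blend ``h = r x_a + (1 - r) x_b`` (fresh ``r ~ U(0,1)`` per pair)
    replaces the worse parent iff ``f(h) < min(f(x_a), f(x_b))``.
    """
    group_pairs = list(combinations(range(len(pop.groups)), 2))
    for k in range(n_pairs):
        ga, gb = group_pairs[k % len(group_pairs)]
        rank = k // len(group_pairs)
        order_a = pop.group_order(ga)
        order_b = pop.group_order(gb)
        ia = int(order_a[min(rank, order_a.size - 1)])
        ib = int(order_b[min(rank, order_b.size - 1)])
        r = rng.random()
        h = r * pop.X[ia] + (1.0 - r) * pop.X[ib]
        outcome = problem.evaluate(h, rng)
        fa, fb = pop.fitness[ia], pop.fitness[ib]
        if outcome.fitness < min(fa, fb):
            worse = ia if fa >= fb else ib
            _log(events, t, "hybridization", ga, pop.fitness[worse], outcome.fitness)
            pop.set_member(worse, h, outcome)


def reorganize_worst(pop: Population, problem, rng, t=0, events=None):
    """Regenerate the group with the highest mean fitness around its own
    best member: ``x <- seed + 0.25 (u - 0.5) (U - L)``, ``u ~ U(0,1)^n``."""
    means = [pop.group_mean_fitness(g) for g in range(len(pop.groups))]
    g = int(np.argmax(means))
    order = pop.group_order(g)
    seed_idx = int(order[0])
    seed = pop.X[seed_idx].copy()
    lower, upper = problem.lower, problem.upper
    for idx in order[1:]:
        u = rng.random(seed.size)
        x_new = np.clip(seed + 0.25 * (u - 0.5) * (upper - lower), lower, upper)
        outcome = problem.evaluate(x_new, rng)
        _log(events, t, "reorganization", g, pop.fitness[idx], outcome.fitness)
        pop.set_member(int(idx), x_new, outcome)


def cooperative_transfer(pop: Population, problem, rng, sigma: float, t=0, events=None):
    """Cyclic donor->receiver transfer.

    In the fixed cycle over groups (exploration -> exploitation -> balance ->
    exploration), each receiver's worst member becomes
    ``0.7 x_best(donor) + 0.3 x_worst(receiver) + N(0, sigma (U - L))``.
    """
    n_groups = len(pop.groups)
    lower, upper = problem.lower, problem.upper
    donors_best = [pop.X[int(pop.group_order(g)[0])].copy() for g in range(n_groups)]
    for recv in range(n_groups):
        donor = (recv - 1) % n_groups
        worst_idx = int(pop.group_order(recv)[-1])
        x_new = 0.7 * donors_best[donor] + 0.3 * pop.X[worst_idx]
        x_new = x_new + rng.normal(0.0, sigma * (upper - lower))
        x_new = np.clip(x_new, lower, upper)
        outcome = problem.evaluate(x_new, rng)
        _log(events, t, "transfer", recv, pop.fitness[worst_idx], outcome.fitness)
        pop.set_member(worst_idx, x_new, outcome)


def elite_local_search(pop: Population, problem, rng, radius: float, t=0, events=None):
    """Shrinking Gaussian probes around the top 10% of the population.

    Each elite spawns one probe ``x' = x + N(0, rho (U - L))`` that replaces
    its parent only on strict improvement; ``rho`` collapses to zero at the
    final iteration.
    """
    k = max(1, int(np.ceil(0.1 * pop.size)))
    elites = np.argsort(pop.fitness, kind="stable")[:k]
    lower, upper = problem.lower, problem.upper
    for idx in elites:
        idx = int(idx)
        probe = pop.X[idx] + rng.normal(0.0, radius * (upper - lower))
        probe = np.clip(probe, lower, upper)
        outcome = problem.evaluate(probe, rng)
        if outcome.fitness < pop.fitness[idx]:
            _log(events, t, "local_search", -1, pop.fitness[idx], outcome.fitness)
            pop.set_member(idx, probe, outcome)


def stagnation_restart(
    pop: Population,
    problem,
    control: ControlState,
    rng,
    delta: float,
    sigma: float,
    fraction: float,
    t=0,
    events=None,
):
    """Reseed the worst ``ceil(fraction * NP)`` members near the incumbent
    best: ``x <- x_best + delta N(0, sigma (U - L))``.  The member currently
    holding the best fitness is never replaced; the stagnation counter
    resets."""
    k = max(1, int(np.ceil(fraction * pop.size)))
    order = np.argsort(pop.fitness, kind="stable")
    best_member = int(order[0])
    worst = [int(i) for i in order[::-1] if int(i) != best_member][:k]
    lower, upper = problem.lower, problem.upper
    for idx in worst:
        x_new = pop.best_x + delta * rng.normal(0.0, sigma * (upper - lower))
        x_new = np.clip(x_new, lower, upper)
        outcome = problem.evaluate(x_new, rng)
        _log(events, t, "restart", -1, pop.fitness[idx], outcome.fitness)
        pop.set_member(idx, x_new, outcome)
    control.stagnation_counter = 0
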