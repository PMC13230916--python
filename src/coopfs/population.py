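"""Population state shared by the main loop and the cooperation operators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EvalOutcome:
    """Scalar fitness of one candidate, with classification accuracy where
    the problem is a feature-selection wrapper (NaN in continuous mode)."""

    fitness: float
    accuracy: float = float("nan")


@dataclass
class Population:
    """Partitioned population with a separately tracked global best.

    ``groups`` holds disjoint index blocks into ``X`` (one per subpopulation,
    in role order).  The global best is kept as a copy so later overwrites of
    the member that produced it never lose the incumbent; with greedy
    replacement everywhere the best fitness is non-increasing over a run.
    """

    X: np.ndarray
    fitness: np.ndarray
    accuracy: np.ndarray
    groups: list
    roles: list
    best_x: np.ndarray = field(default=None)
    best_fitness: float = float("inf")
    best_accuracy: float = float("nan")

    def __post_init__(self):
        if self.best_x is None:
            self.refresh_best()

    @property
    def size(self) -> int:
        return self.X.shape[0]

    def refresh_best(self):
        i = int(np.argmin(self.fitness))
        if self.fitness[i] < self.best_fitness:
            self.best_x = self.X[i].copy()
            self.best_fitness = float(self.fitness[i])
            self.best_accuracy = float(self.accuracy[i])

    def set_member(self, idx: int, x: np.ndarray, outcome: EvalOutcome):
        """Overwrite member ``idx`` and update the incumbent best."""
        self.X[idx] = x
        self.fitness[idx] = outcome.fitness
        self.accuracy[idx] = outcome.accuracy
        if outcome.fitness < self.best_fitness:
            self.best_x = np.array(x, copy=True)
            self.best_fitness = float(outcome.fitness)
            self.best_accuracy = float(outcome.accuracy)

    def group_order(self, g: int) -> np.ndarray:
        """Member indices of group ``g`` sorted best-first."""
        idx = self.groups[g]
        return idx[np.argsort(self.fitness[idx], kind="stable")]

    def group_mean_fitness(self, g: int) -> float:
        return float(self.fitness[self.groups[g]].mean())

    def pbest_pool(self, fraction: float) -> np.ndarray:
        """Rows of the top ``ceil(fraction * NP)`` members by fitness."""
        k = max(1, int(np.ceil(fraction * self.size)))
        order = np.argsort(self.fitness, kind="stable")[:k]
        return self.X[order]
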