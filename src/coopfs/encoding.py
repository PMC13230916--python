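"""Continuous-to-binary encoding and wrapper fitness evaluation.

Candidate feature subsets are encoded as bounded real vectors.  An S-shaped
transfer function maps each coordinate to a selection probability, which a
uniform draw turns into a 0/1 mask.  The mask is scored by stratified
cross-validated accuracy of a classifier restricted to the selected columns,
combined with a subset-size penalty into a single scalar fitness that the
optimizer minimizes:

    f(x) = alpha * (1 - Acc(x)) + (1 - alpha) * |S(x)| / n

with ``alpha`` close to 1 so accuracy dominates and the size term acts as a
regularizer.  Identical masks within a run are served from a cache, and the
inner CV folds are frozen per run, so a mask always maps to one fitness value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "s_transfer",
    "binarize",
    "FitnessWeights",
    "FitnessRecord",
    "FitnessEvaluator",
]


def s_transfer(x):
    """S-shaped transfer function ``1 / (1 + exp(-x/2))``.

    Maps a continuous search coordinate to the probability of selecting the
    corresponding feature.  Accepts scalars or arrays; strictly increasing,
    with ``s_transfer(0) == 0.5``.

    Raises
    ------
    ValueError
        If any input value is not finite.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("s_transfer requires finite input")
    # expit(x/2), written out to avoid overflow warnings for large |x|
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos] / 2.0))
    ex = np.exp(x[~pos] / 2.0)
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def binarize(values, rng):
    """Map a continuous vector to a 0/1 mask by thresholding the transfer
    probabilities against independent uniform draws.

    Bit j is set iff ``s_transfer(values[j]) > u_j`` with ``u_j ~ U(0,1)``.
    An all-zero mask is repaired by switching on the feature with the largest
    transfer probability (lowest index on ties), so every scored subset is
    non-empty.
    """
    values = np.asarray(values, dtype=float)
    prob = s_transfer(values)
    u = rng.random(values.shape[0])
    mask = (prob > u).astype(np.int8)
    if not mask.any():
        mask[int(np.argmax(prob))] = 1
    return mask


def decode_deterministic(values):
    """Deterministic decoding: select feature j iff ``s_transfer(x_j) > 0.5``,
    i.e. iff ``x_j > 0``.  Empty masks are repaired like :func:`binarize`."""
    values = np.asarray(values, dtype=float)
    mask = (values > 0.0).astype(np.int8)
    if not mask.any():
        mask[int(np.argmax(values))] = 1
    return mask


@dataclass(frozen=True)
class FitnessWeights:
    """Weights and classifier choice for the wrapper fitness.

    alpha : accuracy weight in [0, 1]; 1 - alpha weighs the relative subset
        size.  Default 0.99 — accuracy-dominant with a non-zero size penalty.
    classifier_kind : ``"svm"`` (linear SVM, C = 1.0) or
        ``"gradient_boosting"`` (XGBoost: 100 trees, depth 6, lr 0.1,
        subsample 0.8).
    inner_folds : number of stratified inner CV folds (default 5).
    """

    alpha: float = 0.99
    classifier_kind: str = "svm"
    inner_folds: int = 5

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.classifier_kind not in ("svm", "gradient_boosting"):
            raise ValueError(f"unknown classifier_kind {self.classifier_kind!r}")


@dataclass(frozen=True)
class FitnessRecord:
    """Result of scoring one binary mask."""

    fitness: float
    accuracy: float
    subset_size: int
    mask: np.ndarray = field(repr=False)

    @property
    def selected(self):
        return np.flatnonzero(self.mask)


def make_classifier(kind: str, seed: int = 0):
    """Instantiate the wrapper classifier for ``kind``."""
    if kind == "svm":
        return SVC(kernel="linear", C=1.0)
    if kind == "gradient_boosting":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100,
            max_depth=6,
            learning_rate=0.1,
            subsample=0.8,
            random_state=seed,
            verbosity=0,
        )
    raise ValueError(f"unknown classifier kind {kind!r}")


class FitnessEvaluator:
    """Scores binary masks on a labelled matrix with frozen CV folds.

    Parameters
    ----------
    X, y : training matrix (samples x features) and labels.
    weights : :class:`FitnessWeights`.
    seed : seed for the fold split (and the classifier where stochastic);
        the split is drawn once at construction so a mask always receives the
        same accuracy within a run.
    """

    def __init__(self, X, y, weights: FitnessWeights | None = None, seed: int = 0):
        self.X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, y_enc = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("fitness evaluation requires at least 2 classes")
        self.y = y_enc
        self.n_classes = classes.size
        self.weights = weights or FitnessWeights()
        self.seed = seed
        self.n_features = self.X.shape[1]

        min_class = int(np.bincount(self.y).min())
        folds = self.weights.inner_folds
        if min_class < folds:
            logger.warning(
                "smallest class has %d samples < %d folds; reducing fold count",
                min_class,
                folds,
            )
            folds = max(2, min_class)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        self._splits = [
            (tr.copy(), te.copy()) for tr, te in skf.split(self.X, self.y)
        ]
        self._cache: dict[bytes, FitnessRecord] = {}
        self.n_evaluations = 0  # classifier CV runs actually performed

    def cv_accuracy(self, columns) -> float:
        """Mean stratified CV accuracy of the classifier on the given
        feature columns (the frozen per-run splits)."""
        Xs = self.X[:, columns]
        accs = []
        for tr, te in self._splits:
            clf = make_classifier(self.weights.classifier_kind, self.seed)
            clf.fit(Xs[tr], self.y[tr])
            accs.append(float(np.mean(clf.predict(Xs[te]) == self.y[te])))
        return float(np.mean(accs))

    def evaluate_mask(self, mask) -> FitnessRecord:
        mask = np.asarray(mask, dtype=np.int8)
        if not mask.any():
            raise ValueError("empty masks must be repaired before scoring")
        key = mask.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        selected = np.flatnonzero(mask)
        acc = self.cv_accuracy(selected)
        self.n_evaluations += 1
        w = self.weights
        fitness = w.alpha * (1.0 - acc) + (1.0 - w.alpha) * (
            selected.size / self.n_features
        )
        record = FitnessRecord(
            fitness=float(fitness),
            accuracy=acc,
            subset_size=int(selected.size),
            mask=mask.copy(),
        )
        self._cache[key] = record
        return record

    def evaluate(self, values, rng) -> FitnessRecord:
        """Binarize a continuous vector and score the resulting mask."""
        return self.evaluate_mask(binarize(values, rng))
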