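"""Stage-1 filter: Fisher-score feature ranking.

The Fisher score of a feature is the ratio of its between-class to
within-class variance,

    FS_i = sum_c n_c (mu_{c,i} - mu_i)^2 / (sum_c n_c sigma^2_{c,i} + eps),

with population (biased) class variances, matching the ``n_c`` weighting of
the numerator.  A tiny ``eps`` guards features whose within-class variance is
exactly zero; such perfectly separating features receive very large scores and
rank first.  The filter keeps the ``subset_size`` highest-scoring features and
hands them to the wrapper stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EPS_DENOM = 1e-12

__all__ = ["FisherScoreTable", "fisher_scores", "select_top", "write_ranking"]


@dataclass(frozen=True)
class FisherScoreTable:
    """Per-feature Fisher scores plus the class statistics behind them."""

    scores: np.ndarray
    class_counts: np.ndarray
    class_means: np.ndarray  # (n_classes, n_features)
    class_variances: np.ndarray  # population variances, (n_classes, n_features)
    global_means: np.ndarray

    @property
    def n_features(self) -> int:
        return self.scores.size


def fisher_scores(X, y) -> FisherScoreTable:
    """Compute Fisher scores for every column of ``X`` given labels ``y``.

    Raises
    ------
    ValueError
        If fewer than two classes are present.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_enc = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("Fisher scoring requires at least 2 classes")

    counts = np.bincount(y_enc).astype(float)
    n_classes = classes.size
    n_features = X.shape[1]
    means = np.empty((n_classes, n_features))
    variances = np.empty((n_classes, n_features))
    for c in range(n_classes):
        Xc = X[y_enc == c]
        means[c] = Xc.mean(axis=0)
        variances[c] = Xc.var(axis=0)  # population variance (ddof=0)
    global_means = X.mean(axis=0)

    between = (counts[:, None] * (means - global_means) ** 2).sum(axis=0)
    within = (counts[:, None] * variances).sum(axis=0)
    scores = between / (within + EPS_DENOM)
    return FisherScoreTable(
        scores=scores,
        class_counts=counts.astype(int),
        class_means=means,
        class_variances=variances,
        global_means=global_means,
    )


def select_top(table: FisherScoreTable, subset_size: int) -> np.ndarray:
    """Indices of the ``subset_size`` highest-scoring features.

    Ordered by descending score; ties broken by ascending original index.
    If ``subset_size`` exceeds the feature count, all features are returned
    (with a logged warning).
    """
    if subset_size < 1:
        raise ValueError("subset_size must be >= 1")
    n = table.n_features
    if subset_size > n:
        logger.warning(
            "requested top %d of only %d features; keeping all", subset_size, n
        )
        subset_size = n
    # stable sort on -score preserves ascending-index order among ties
    order = np.argsort(-table.scores, kind="stable")
    return order[:subset_size]


def write_ranking(table: FisherScoreTable, path, feature_names=None) -> None:
    """Emit a two-column TSV (feature name, Fisher score), best first."""
    order = np.argsort(-table.scores, kind="stable")
    if feature_names is None:
        feature_names = [f"f{i + 1}" for i in range(table.n_features)]
    names = np.asarray(feature_names, dtype=object)
    pd.DataFrame(
        {"feature": names[order], "fisher_score": table.scores[order]}
    ).to_csv(path, sep="\t", index=False)
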