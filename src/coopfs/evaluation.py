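"""Evaluation protocol and comparison statistics.

Covers the leakage-free nested cross-validation used to score feature
selectors (filter and wrapper fitted on the training folds only), multi-run
aggregation, and the nonparametric method-comparison statistics: Wilcoxon
signed-rank tests with zero-splitting, Holm's step-down correction, and
Friedman mean ranks across datasets.  It also provides one-factor
sensitivity sweeps and the ablation harness that toggles individual
mechanisms of the optimizer.

Zero differences in the Wilcoxon test follow the zsplit convention: zeros
keep their tie-averaged low ranks and contribute half of that rank mass to
each of R+ and R-, so R+ + R- = n(n+1)/2 always holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .encoding import make_classifier
from .optimizer import OptimizerConfig, select_features

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseTestResult",
    "wilcoxon_signed_rank",
    "holm_correction",
    "compare_to_reference",
    "friedman_ranks",
    "nested_evaluation",
    "wrapper_selector",
    "ablation_harness",
    "apply_variant",
    "sensitivity_sweep",
    "ABLATION_VARIANTS",
]


# ---------------------------------------------------------------------------
# pairwise and multiple-method statistics
# ---------------------------------------------------------------------------

@dataclass
class PairwiseTestResult:
    """One Wilcoxon signed-rank comparison (reference minus competitor)."""

    comparison: str
    r_plus: float
    r_minus: float
    statistic: float
    p_value: float
    holm_p: float = float("nan")
    decision: str = ""


def wilcoxon_signed_rank(a, b, comparison: str = "") -> PairwiseTestResult:
    """Paired two-sided Wilcoxon signed-rank test with zero-splitting.

    ``a`` and ``b`` are paired measurements (e.g. per-dataset mean
    accuracies of two methods).  Magnitude ranks use average ranks on ties;
    exactly-zero differences keep their tie-averaged lowest ranks and half
    their total rank mass goes to each of R+ and R-.  The statistic is
    ``min(R+, R-)``; the p-value is exact for small tie-free samples and a
    normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 6:
        raise ValueError("need at least 6 pairs for a meaningful test")
    d = a - b
    total = n * (n + 1) / 2.0

    if np.all(d == 0):
        logger.warning("all paired differences are zero: degenerate comparison")
        return PairwiseTestResult(
            comparison=comparison,
            r_plus=total / 2.0,
            r_minus=total / 2.0,
            statistic=total / 2.0,
            p_value=1.0,
            decision="degenerate",
        )

    ranks = stats.rankdata(np.abs(d))
    r_zero = float(ranks[d == 0].sum())
    r_plus = float(ranks[d > 0].sum()) + r_zero / 2.0
    r_minus = float(ranks[d < 0].sum()) + r_zero / 2.0
    res = stats.wilcoxon(a, b, zero_method="zsplit")
    return PairwiseTestResult(
        comparison=comparison,
        r_plus=r_plus,
        r_minus=r_minus,
        statistic=min(r_plus, r_minus),
        p_value=float(res.pvalue),
    )


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control);
    element-wise >= the raw p-values and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def compare_to_reference(table: pd.DataFrame, reference: str, alpha: float = 0.05) -> pd.DataFrame:
    """Wilcoxon–Holm comparison of every method against ``reference``.

    ``table`` is methods x datasets (accuracies, %).  Returns one row per
    competitor with R+, R-, the statistic, raw and Holm-adjusted p-values,
    and the reject/accept decision at level ``alpha``.
    """
    if reference not in table.index:
        raise ValueError(f"reference method {reference!r} not in table")
    ref = table.loc[reference].to_numpy(dtype=float)
    results = []
    for method in table.index:
        if method == reference:
            continue
        results.append(
            wilcoxon_signed_rank(
                ref, table.loc[method].to_numpy(dtype=float), comparison=method
            )
        )
    adjusted = holm_correction([r.p_value for r in results])
    for r, hp in zip(results, adjusted):
        r.holm_p = float(hp)
        if r.decision != "degenerate":
            r.decision = "rejected" if hp < alpha else "accepted"
    return pd.DataFrame(
        {
            "comparison": [r.comparison for r in results],
            "r_plus": [r.r_plus for r in results],
            "r_minus": [r.r_minus for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "holm_p": [r.holm_p for r in results],
            "decision": [r.decision for r in results],
        }
    ).set_index("comparison")


def friedman_ranks(table: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Friedman rank analysis of a methods x datasets accuracy table.

    Methods are ranked within each dataset (rank 1 = highest accuracy,
    average ranks on ties).  Returns (summary, chi-square, p-value) where
    the summary holds each method's mean rank, overall standing, and a 95%
    t-interval on its per-dataset accuracies.
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 methods and 2 datasets")
    acc = table.to_numpy(dtype=float)
    k, n_data = acc.shape
    ranks = np.apply_along_axis(lambda col: stats.rankdata(-col), 0, acc)
    mean_ranks = ranks.mean(axis=1)

    rank_sums = ranks.sum(axis=1)
    chi2 = 12.0 / (n_data * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n_data * (k + 1)
    p_value = float(stats.chi2.sf(chi2, k - 1))

    t_crit = stats.t.ppf(0.975, n_data - 1)
    means = acc.mean(axis=1)
    half = t_crit * acc.std(axis=1, ddof=1) / np.sqrt(n_data)
    summary = pd.DataFrame(
        {
            "mean_rank": mean_ranks,
            "overall_rank": stats.rankdata(mean_ranks),
            "mean_accuracy": means,
            "ci_low": means - half,
            "ci_high": means + half,
        },
        index=table.index,
    ).sort_values("mean_rank")
    return summary, float(chi2), p_value


# ---------------------------------------------------------------------------
# nested cross-validated evaluation of a feature selector
# ---------------------------------------------------------------------------

def wrapper_selector(config: OptimizerConfig):
    """Build a selector callable for :func:`nested_evaluation` from the
    two-stage pipeline: ``selector(X_train, y_train, seed) -> indices``."""

    def selector(X_tr, y_tr, seed: int):
        cfg = replace(config, seed=int(seed))
        return select_features(X_tr, y_tr, cfg).selected_indices

    return selector


def nested_evaluation(
    X,
    y,
    selector,
    classifier_kind: str = "svm",
    runs: int = 30,
    outer_folds: int = 5,
    seed: int = 42,
) -> pd.DataFrame:
    """Leakage-free nested evaluation of a feature selector.

    Per run r (seeded ``seed + r``): a stratified ``outer_folds``-fold split;
    on each fold the selector sees only the training rows, a fresh classifier
    is fitted on the training rows restricted to the selected columns, and
    accuracy is measured on the untouched test fold.  Run accuracy is the
    fold mean.  Returns a frame with one row per run (accuracy in [0, 1] and
    the mean selected-subset size).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_enc = np.unique(y, return_inverse=True)
    counts = np.bincount(y_enc)
    for cls, cnt in zip(classes, counts):
        if cnt < outer_folds:
            raise ValueError(
                f"class {cls!r} has {cnt} samples, fewer than {outer_folds} outer folds"
            )

    rows = []
    for r in range(runs):
        run_seed = seed + r
        skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=run_seed)
        fold_accs, sizes = [], []
        for tr, te in skf.split(X, y_enc):
            cols = np.asarray(selector(X[tr], y_enc[tr], run_seed))
            clf = make_classifier(classifier_kind, run_seed)
            clf.fit(X[np.ix_(tr, cols)], y_enc[tr])
            pred = clf.predict(X[np.ix_(te, cols)])
            fold_accs.append(float(np.mean(pred == y_enc[te])))
            sizes.append(cols.size)
        rows.append(
            {
                "run": r,
                "seed": run_seed,
                "accuracy": float(np.mean(fold_accs)),
                "mean_subset_size": float(np.mean(sizes)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ablation and sensitivity harnesses
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = {
    "full": {},
    "-LF": {"use_levy": False},
    "-AD": {"use_adaptive": False},
    "-CO": {"use_cooperation": False},
    "-REO": {"use_reorganization": False},
    "-RS": {"use_restart_local": False},
    "2SP": {"subpop_count": 2},
    "4SP": {"subpop_count": 4},
    "no-filter": {"use_fisher_filter": False},
}


def apply_variant(config: OptimizerConfig, variant: str) -> OptimizerConfig:
    """Return a config with one ablation variant applied (see
    :data:`ABLATION_VARIANTS` for the names)."""
    key = variant.strip()
    key = key if key in ABLATION_VARIANTS else key.upper()
    if key.startswith("–"):  # tolerate en-dash spellings
        key = "-" + key[1:]
    if key not in ABLATION_VARIANTS:
        raise ValueError(f"unknown ablation variant {variant!r}")
    return replace(config, **ABLATION_VARIANTS[key])


def ablation_harness(X, y, base_config: OptimizerConfig, variants, runs: int = 5) -> pd.DataFrame:
    """Run each ablation variant under identical seeds and report mean/std
    accuracy (%) and mean subset size, one row per variant."""
    rows = []
    for variant in variants:
        cfg = apply_variant(base_config, variant)
        accs, sizes = [], []
        for r in range(runs):
            res = select_features(X, y, replace(cfg, seed=base_config.seed + r))
            accs.append(res.accuracy * 100.0)
            sizes.append(res.subset_size)
        rows.append(
            {
                "variant": variant,
                "mean_accuracy": float(np.mean(accs)),
                "std_accuracy": float(np.std(accs, ddof=1)) if runs > 1 else 0.0,
                "mean_subset_size": float(np.mean(sizes)),
            }
        )
    return pd.DataFrame(rows).set_index("variant")


_SWEEP_ALIASES = {
    "T_hyb": ("coop", "hybrid_period"),
    "T_coop": ("coop", "coop_period"),
    "T_reorg": ("coop", "reorg_period"),
    "T_local": ("coop", "local_period"),
    "T_stag": ("coop", "stagnation_limit"),
    "rho_restart": ("coop", "restart_fraction"),
    "lambda": (None, "elite_pull"),
}


def sensitivity_sweep(X, y, config: OptimizerConfig, parameter: str, grid, runs: int = 5) -> pd.DataFrame:
    """One-factor-at-a-time sweep of ``parameter`` over ``grid``, all other
    settings at their defaults; mean +/- std accuracy (%) per grid point."""
    grid = list(grid)
    if not grid:
        raise ValueError("empty sweep grid")
    target = _SWEEP_ALIASES.get(parameter)
    if target is None:
        if not hasattr(config, parameter):
            raise ValueError(f"unknown parameter {parameter!r}")
        target = (None, parameter)

    rows = []
    for value in grid:
        section, name = target
        if section == "coop":
            cast = int if isinstance(getattr(config.coop, name), int) else float
            cfg = replace(config, coop=replace(config.coop, **{name: cast(value)}))
        else:
            cfg = replace(config, **{name: value})
        accs = []
        for r in range(runs):
            res = select_features(X, y, replace(cfg, seed=config.seed + r))
            accs.append(res.accuracy * 100.0)
        rows.append(
            {
                "parameter": parameter,
                "value": value,
                "mean_accuracy": float(np.mean(accs)),
                "std_accuracy": float(np.std(accs, ddof=1)) if runs > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
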