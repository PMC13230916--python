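"""Dataset readers, result writers, and bundled reference tables."""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import numpy as np
import pandas as pd


def load_labelled_csv(path, label_col: str = "label", sep=None):
    """Read a delimited text matrix (one row per sample, numeric feature
    columns) with a named class-label column.

    Returns ``(X, y, feature_names)``.  The delimiter is sniffed from the
    extension unless ``sep`` is given.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if label_col not in df.columns:
        raise KeyError(f"label column {label_col!r} not found in {path}")
    y = df[label_col].to_numpy()
    features = df.drop(columns=[label_col])
    return features.to_numpy(dtype=float), y, list(features.columns)


def load_last_column_labelled(path, sep=None):
    """Read the common microarray-export convention where the final column
    is the class label (header optional)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    y = df.iloc[:, -1].to_numpy()
    features = df.iloc[:, :-1]
    return features.to_numpy(dtype=float), y, [str(c) for c in features.columns]


def reference_accuracy_table() -> pd.DataFrame:
    """Bundled reference comparison table: published mean cross-validated
    accuracies (%) of 16 wrapper feature-selection methods on 12 public
    microarray datasets; rows are methods, columns datasets."""
    with resources.files("coopfs.data").joinpath("microarray_accuracy.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def reference_classifier_table() -> pd.DataFrame:
    """Bundled reference table of per-dataset mean accuracies (%) of the
    two wrapper classifiers (XGBoost and SVM) on the same 12 datasets."""
    with resources.files("coopfs.data").joinpath("classifier_accuracy.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def write_trace_tsv(trace, path) -> None:
    """Write the per-iteration run trace as TSV: iteration, best fitness,
    best accuracy, and per-subpopulation success ratios."""
    n_groups = trace.success_ratio.shape[1] if trace.success_ratio.size else 0
    cols = {
        "iteration": np.arange(1, trace.best_fitness.size + 1),
        "best_fitness": trace.best_fitness,
        "best_accuracy": trace.best_accuracy,
    }
    names = ["R_exp", "R_expn", "R_bal", "R_bal2"]
    for g in range(n_groups):
        cols[names[g] if g < len(names) else f"R_{g}"] = trace.success_ratio[:, g]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, config: dict, seed: int, input_digest: str,
                   started: str = "", finished: str = "") -> None:
    """Write the run manifest pairing every results file with what is
    needed to re-run it bit-identically.  The start/end markers are
    informational only; no result depends on wall-clock time."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "input_sha256": input_digest,
        "version": __version__,
        "started": started,
        "finished": finished,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
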