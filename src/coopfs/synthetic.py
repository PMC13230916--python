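"""Synthetic gene-expression generator with planted ground truth.

Emulates the shape of public microarray classification datasets — tens of
samples, thousands of features, 2–4 roughly balanced classes — with three
feature strata:

* informative — class c is drawn N(c * effect_size, 1), so consecutive
  class means are ``effect_size`` noise-SDs apart;
* redundant — random positive mixtures of the informative features plus
  N(0, redundancy_noise), i.e. correlated proxies carrying no new signal;
* noise — N(0, 1) independent of the labels.

The planted informative and redundant index sets are returned, enabling
recovery experiments with a known answer.  Everything is a deterministic
function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SyntheticSpec", "generate_expression_data", "write_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator condition set.

    Defaults describe the small two-class recovery scenario used throughout:
    60 samples, 1,000 features of which 5 are informative at effect size 2.
    """

    n_samples: int = 60
    n_features: int = 1000
    n_classes: int = 2
    n_informative: int = 5
    n_redundant: int = 0
    effect_size: float = 2.0
    redundancy_noise: float = 0.5
    class_proportions: tuple = None
    seed: int = 0

    def __post_init__(self):
        if not 2 <= self.n_classes <= 4:
            raise ValueError("n_classes must lie in 2..4")
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("informative + redundant exceeds n_features")
        props = self.class_proportions
        if props is not None:
            props = tuple(float(p) for p in props)
            if len(props) != self.n_classes:
                raise ValueError("class_proportions length must equal n_classes")
            if not np.isclose(sum(props), 1.0):
                raise ValueError("class_proportions must sum to 1")
            object.__setattr__(self, "class_proportions", props)

    def proportions(self) -> np.ndarray:
        if self.class_proportions is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.class_proportions)


def _class_counts(spec: SyntheticSpec) -> np.ndarray:
    """Largest-remainder apportionment of samples to classes — exact
    proportions up to rounding, every class non-empty."""
    props = spec.proportions()
    raw = props * spec.n_samples
    counts = np.floor(raw).astype(int)
    remainder = spec.n_samples - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    if (counts == 0).any():
        raise ValueError("a class received zero samples; adjust proportions")
    return counts


def generate_expression_data(spec: SyntheticSpec):
    """Generate one labelled matrix.

    Returns
    -------
    X : (n_samples, n_features) float array
    y : (n_samples,) integer labels 0..n_classes-1
    informative : planted informative feature indices
    redundant : planted redundant feature indices
    """
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec)
    y = np.repeat(np.arange(spec.n_classes), counts)

    n, p = spec.n_samples, spec.n_features
    X = rng.normal(size=(n, p))

    informative = np.arange(spec.n_informative)
    redundant = np.arange(spec.n_informative, spec.n_informative + spec.n_redundant)

    # class-mean offsets: consecutive classes effect_size apart
    X[:, informative] += (y[:, None] * spec.effect_size)

    if spec.n_redundant:
        mix = rng.random((spec.n_informative, spec.n_redundant))
        mix /= mix.sum(axis=0)  # positive mixtures of the informative block
        X[:, redundant] = X[:, informative] @ mix + rng.normal(
            0.0, spec.redundancy_noise, size=(n, spec.n_redundant)
        )

    perm = rng.permutation(n)
    return X[perm], y[perm], informative, redundant


def write_dataset(spec: SyntheticSpec, csv_path, sidecar_path=None) -> None:
    """Write the generated matrix as CSV with a ``label`` column plus a JSON
    sidecar naming the planted indices."""
    X, y, informative, redundant = generate_expression_data(spec)
    cols = [f"f{i + 1}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    df["label"] = y
    df.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "informative": [int(i) for i in informative],
                    "redundant": [int(i) for i in redundant],
                    "seed": spec.seed,
                },
                fh,
                indent=2,
            )
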