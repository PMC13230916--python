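import numpy as np
import pytest

from coopfs import OptimizerConfig, SyntheticSpec, generate_expression_data


@pytest.fixture(scope="session")
def small_dataset():
    """40 samples x 60 features, 4 informative at effect size 2, 2 classes."""
    spec = SyntheticSpec(
        n_samples=40,
        n_features=60,
        n_classes=2,
        n_informative=4,
        n_redundant=4,
        effect_size=2.0,
        seed=11,
    )
    X, y, informative, redundant = generate_expression_data(spec)
    return X, y, informative, redundant


@pytest.fixture()
def tiny_config():
    """A configuration small enough for sub-second wrapper runs."""
    return OptimizerConfig(
        population_size=12,
        max_iterations=6,
        seed=5,
        filter_size=25,
        inner_folds=3,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
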