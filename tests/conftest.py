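import numpy as np
import pytest

from rwdiffmap import WeightedDataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset(rng):
    """20 samples, 3 variables, unit weights."""
    return WeightedDataset(rng.normal(size=(20, 3)))


@pytest.fixture
def weighted_dataset(rng):
    """15 samples, 4 variables, nonuniform positive weights."""
    samples = rng.normal(size=(15, 4))
    weights = rng.uniform(0.2, 3.0, size=15)
    return WeightedDataset(samples, weights)


def random_weighted_dataset(rng, n_samples=None, n_variables=None, biased=True):
    n_samples = n_samples or int(rng.integers(3, 40))
    n_variables = n_variables or int(rng.integers(1, 8))
    samples = rng.normal(size=(n_samples, n_variables))
    weights = rng.uniform(0.1, 5.0, size=n_samples) if biased else None
    return WeightedDataset(samples, weights)
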