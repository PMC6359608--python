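import numpy as np
import pytest

import eegstate as es


@pytest.fixture(scope="session")
def fb():
    return es.sym4_filter_bank()


@pytest.fixture(scope="session")
def small_dataset():
    """120 synthetic segments (40/40/40 + shorter signals) for fast tests."""
    return es.generate_dataset({-1: 40, 0: 40, 1: 40}, n_samples=1024, seed=11)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    X, y = es.extract_features(small_dataset)
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def separable_features(rng, n_per_class=20, noise=0.3):
    """Well-separated 3-class Gaussian blobs in 10-D.

    Each class has its own exclusive high axis, so every class is
    isolable by a single axis-aligned split — a regime where greedy
    trees cannot be distracted by noise features.
    """
    centers = {-1: np.eye(10)[0] * 4.0, 0: np.eye(10)[1] * 4.0,
               1: np.eye(10)[2] * 4.0}
    y = np.repeat([-1, 0, 1], n_per_class)
    X = np.vstack([centers[c] + noise * rng.normal(size=10) for c in y])
    return X, y
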