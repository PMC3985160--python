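import numpy as np
import pytest

from protelm.elm import Dataset
from protelm.synthetic import generate_dataset, make_profiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, well-separated 3-class dataset for learning sanity checks."""
    profiles = make_profiles(3, separation=0.8, seed=7)
    synth = generate_dataset(profiles, [25, 25, 25], seed=7)
    from protelm.features import FeatureScaler, feature_matrix

    X = FeatureScaler().fit_transform(feature_matrix(synth.records))
    return Dataset.from_arrays(X, np.asarray(synth.labels, dtype=object))


def random_classification(rng, N, d, C):
    """Random features with labels from a noisy linear rule."""
    X = rng.uniform(-1, 1, size=(N, d))
    w = rng.normal(size=(d, C))
    labels = np.argmax(X @ w + 0.1 * rng.normal(size=(N, C)), axis=1)
    return X, np.asarray([f"c{i}" for i in labels], dtype=object)
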