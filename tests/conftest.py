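import numpy as np
import pytest

from normsmote import Dataset, FixtureSpec, make_gaussian_imbalanced


@pytest.fixture
def wpbc_shaped():
    """Imbalanced Gaussian fixture with the 45/149 count shape."""
    return make_gaussian_imbalanced(FixtureSpec(n_minority=45, n_majority=149, r=8,
                                                separation=2.0, seed=11))


@pytest.fixture
def pima_shaped():
    """Imbalanced Gaussian fixture with the 268/500 count shape."""
    return make_gaussian_imbalanced(FixtureSpec(n_minority=268, n_majority=500, r=8,
                                                separation=2.0, seed=12))


@pytest.fixture
def tiny_dataset():
    feats = np.array([[0.0, 10.0], [1.0, 20.0], [2.0, 30.0], [3.0, 40.0]])
    labels = np.array(["a", "a", "b", "b"])
    return Dataset(feats, labels, minority_label="a")
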