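import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from unshrunk import DataMatrix, sample_correlation
from unshrunk.shrinkage import ShrinkageModel, _sorted_eigh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_data(rng):
    """Factory: n x p standard-normal DataMatrix (optionally correlated)."""

    def make(n, p, correlated=False, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        X = r.standard_normal((n, p))
        if correlated:
            mix = np.eye(p) + 0.4 * np.triu(np.ones((p, p)), 1)
            X = X @ mix
        return DataMatrix(X)

    return make


def model_from_matrix(R, names=None):
    """ShrinkageModel straight from a correlation matrix (no data)."""
    R = np.asarray(R, dtype=float)
    vals, vecs = _sorted_eigh(R)
    names = names or [f"V{j + 1}" for j in range(R.shape[0])]
    return ShrinkageModel(R, vals, vecs, names)


@pytest.fixture
def singular_model(gaussian_data):
    """Factory: model with a singular sample correlation (n <= p)."""

    def make(n, p, seed):
        return sample_correlation(gaussian_data(n, p, seed=seed))

    return make
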