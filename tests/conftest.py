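import numpy as np
import pytest

from siagmm import Dataset, GMMParams


def random_gmm(rng, K, p, scale=1.0, sep=3.0) -> GMMParams:
    """A random valid GMM with reasonably conditioned covariances."""
    w = rng.dirichlet(np.ones(K) * 5.0)
    means = rng.normal(scale=sep, size=(K, p))
    A = rng.normal(size=(K, p, p)) * scale
    covs = A @ np.swapaxes(A, -1, -2) + (0.5 + scale) * np.eye(p)
    return GMMParams(w, means, covs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_blob_data(rng):
    """Well-specified, well-separated 2-component data with labels."""
    n = 400
    X = np.vstack(
        [rng.normal([0, 0], 1.0, (n // 2, 2)), rng.normal([8, 8], 1.0, (n // 2, 2))]
    )
    labels = np.repeat([0, 1], n // 2)
    return Dataset(X, labels)
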