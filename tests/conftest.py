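import numpy as np
import pytest

from logsumreg import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng):
    """A dense 40x8 regression instance with a known sparse truth."""
    X = rng.standard_normal((40, 8))
    beta = np.array([3.0, -2.0, 0.0, 0.0, 1.5, 0.0, 0.0, 0.0])
    y = X @ beta + 0.1 * rng.standard_normal(40)
    names = [f"d{j}" for j in range(8)]
    return Dataset(X=X, y=y, names=names), beta


@pytest.fixture
def orthonormal_dataset(rng):
    """Design with X^T X / n = I after standardization.

    Built from the Q factor of a random matrix, then rescaled so each
    column has mean 0 and mean-square 1 while remaining orthogonal.
    """
    n, p = 60, 10
    m = np.hstack([np.ones((n, 1)), rng.standard_normal((n, p))])
    q, _ = np.linalg.qr(m)
    # columns 1..p are orthonormal and orthogonal to the constant vector,
    # so they have exact mean 0; scaling by sqrt(n) gives mean-square 1
    X = q[:, 1:] * np.sqrt(n)
    beta = np.linspace(-3, 3, p)
    y = X @ beta + 0.05 * rng.standard_normal(n)
    return Dataset(X=X, y=y)
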