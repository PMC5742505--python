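import numpy as np
import pytest

from kin import PenaltyConfig, ScenarioSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_logistic_data(rng):
    """Well-conditioned, non-separable logistic problem (n=200, p=3)."""
    X = rng.standard_normal((200, 3))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    beta = np.array([0.8, -0.5, 0.2])
    eta = 0.3 + X @ beta
    y = (rng.random(200) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return X, y


@pytest.fixture
def separable_toy():
    """Two well-separated Gaussian blobs in 2-d."""
    rng = np.random.default_rng(7)
    n = 40
    X0 = rng.normal([-3.0, -3.0], 0.5, size=(n, 2))
    X1 = rng.normal([3.0, 3.0], 0.5, size=(n, 2))
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], n)
    perm = rng.permutation(2 * n)
    return X[perm], y[perm]


@pytest.fixture
def sparse_scenario():
    """The very sparse study configuration: 2 signal features among 100."""
    return ScenarioSpec(p=100, sparsity=0.98, n=100, class1_ratio=0.5, rho=0.8,
                        n_reps=3, seed=11)


@pytest.fixture
def fast_cfg():
    """Penalty config with a short path for quick end-to-end tests."""
    return PenaltyConfig(n_lambda=25)
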