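import numpy as np
import pytest

from ertmap import make_fixture


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_fixture("tiny", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def tiny_datasets(n_sets: int = 8, seed: int = 99):
    """Random tiny (n <= 12, p <= 3) regression problems for oracle checks,
    including duplicated columns and tied values."""
    rng = np.random.default_rng(seed)
    sets = []
    for k in range(n_sets):
        n = int(rng.integers(6, 13))
        p = int(rng.integers(1, 4))
        X = rng.normal(size=(n, p))
        if k % 3 == 0 and p >= 2:
            X[:, 1] = X[:, 0]  # exact duplicate -> perfect surrogate
        if k % 4 == 0:
            X = np.round(X, 1)  # induce ties
        y = X[:, 0] * rng.normal(1, 0.5) + rng.normal(size=n)
        if k % 5 == 0:
            y = np.round(y, 1)
        sets.append((X, y))
    return sets
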