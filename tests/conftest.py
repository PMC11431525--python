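import itertools

import numpy as np
import pytest

from subsetvi import Dataset


def random_instance(rng, n=None, p=None, noise=None):
    """A random regression dataset with mildly correlated columns and a
    sparse true coefficient vector; used throughout as generic test input."""
    n = int(rng.integers(30, 201)) if n is None else n
    p = int(rng.integers(2, 9)) if p is None else p
    mix = np.eye(p) + 0.4 * rng.standard_normal((p, p)) / np.sqrt(p)
    X = rng.standard_normal((n, p)) @ mix
    beta = rng.standard_normal(p) * rng.binomial(1, 0.5, p)
    noise = (0.5 + rng.random()) if noise is None else noise
    y = X @ beta + noise * rng.standard_normal(n)
    return Dataset(y=y, X=X, names=tuple(f"v{j}" for j in range(p)))


def brute_force_best_subset(X, y, lam, forced_in=(), forced_out=()):
    """Independent enumeration oracle: dense least squares on the raw design
    for every admissible subset, size-major order, ties to the first seen.

    Deliberately shares no code with the package's Gram/sweep machinery.
    """
    n, p = X.shape
    free = [j for j in range(p) if j not in forced_in and j not in forced_out]
    best = None
    for k in range(len(free) + 1):
        for comb in itertools.combinations(free, k):
            active = tuple(sorted(set(forced_in) | set(comb)))
            Z = np.column_stack([np.ones(n)] + [X[:, j] for j in active])
            coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
            resid = y - Z @ coef
            rss = float(resid @ resid)
            q = n * (np.log(2 * np.pi * rss / n) + 1) + lam * len(active)
            if best is None or q < best[0] - 1e-9:
                best = (q, active, rss, coef)
    return best  # (q, active, rss, coef)


@pytest.fixture
def rng():
    return np.random.default_rng(20240919)
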