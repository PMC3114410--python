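"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pathweight import make_synthetic_study


def brute_force_Q(X, Y) -> float:
    """Independent double-loop evaluation of the global-test statistic.

    Q = (1/mu2) * sum_i sum_j R_ij (Y_i - mu)(Y_j - mu) with
    R = (1/m) X X', mu = mean(Y), mu2 = mu(1 - mu).  Written with explicit
    Python loops so it shares no code path with the matrix implementation.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, m = X.shape
    mu = sum(Y) / n
    mu2 = mu * (1.0 - mu)
    total = 0.0
    for i in range(n):
        for j in range(n):
            r_ij = sum(X[i, k] * X[j, k] for k in range(m)) / m
            total += r_ij * (Y[i] - mu) * (Y[j] - mu)
    return total / mu2


def random_instance(rng, n=6, m=3):
    """A random Gaussian pathway matrix with balanced labels."""
    X = rng.standard_normal((n, m))
    Y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    return X, Y


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A 5-pathway study with one planted informative pathway."""
    return make_synthetic_study(
        n_genes=120, n_pathways=5, pathway_size_range=(6, 12), n_samples=30,
        n_informative_pathways=1, shift_size=2.0, seed=7)
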