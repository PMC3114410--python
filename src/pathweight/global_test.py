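r"""The global test for one gene set and its permutation p-value.

The test asks whether samples with similar expression profiles over a gene
set also have similar phenotypes.  For an n x m pathway matrix X and a
binary outcome Y (1 = disease, 0 = normal) the statistic is the quadratic
form

    Q = (1/mu2) * (Y - mu)' R (Y - mu),        R = (1/m) X X',

with mu = mean(Y) the null expectation of Y and mu2 = mu * (1 - mu) its
null variance (the Bernoulli second central moment; since mu2 is a
constant for a fixed Y, the permutation p-value is identical under any
other constant scaling of Q).  Significance is assessed by permuting Y:
the p-value is the fraction of permutations whose Q is at least the
observed Q.  No +1 correction is applied, so p = 0 is attainable; report
"< 1/B" alongside when presenting such values.

For n <= 10 an exact oracle enumerates all C(n, n1) distinct label
arrangements instead of sampling them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import comb

__all__ = [
    "GlobalTestResult",
    "compute_Q",
    "permutation_p_value",
    "exact_permutation_p_value",
    "make_permutation_stream",
    "q_for_permutations",
]

_EXACT_MAX_N = 10

# Permutations that realize the observed arrangement must count as ties, but
# the vectorized permuted-Q path and the observed-Q path round differently at
# the last ulp; comparisons therefore allow a relative slack far below any
# meaningful Q difference.
_TIE_RTOL = 1e-9


def count_at_least(q_perm, q_obs: float) -> int:
    """#{b : Q_b >= Q_obs}, tolerant to last-ulp rounding of exact ties."""
    return int(np.count_nonzero(
        np.asarray(q_perm) >= q_obs - _TIE_RTOL * (1.0 + abs(q_obs))))


@dataclass
class GlobalTestResult:
    q_observed: float
    p_value: float
    n_permutations: int
    mu: float
    mu2: float
    seed: int | None = None


def _validate(X, Y):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    if X.ndim != 2:
        raise ValueError("X must be an n x m matrix")
    n, m = X.shape
    if m < 1:
        raise ValueError("X must have at least one gene column")
    if Y.shape != (n,):
        raise ValueError(f"Y has shape {Y.shape}, expected ({n},)")
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("Y must be binary 0/1")
    if Y.min() == Y.max():
        raise ValueError("both classes must be present (mu2 = 0 otherwise)")
    return X, Y.astype(float)


def compute_Q(X, Y) -> float:
    """Quadratic-form statistic Q = (Y-mu)' X X' (Y-mu) / (m * mu2).

    Equals the explicit double sum over R_ij (Y_i - mu)(Y_j - mu) / mu2;
    computed as a squared norm, ||X'(Y - mu)||^2 / (m * mu2), since R is
    positive semi-definite.
    """
    X, Y = _validate(X, Y)
    n, m = X.shape
    mu = Y.mean()
    mu2 = mu * (1.0 - mu)
    z = Y - mu
    v = X.T @ z
    return float(v @ v) / (m * mu2)


def make_permutation_stream(n: int, n_perm: int, seed) -> np.ndarray:
    """n_perm uniform shuffles of range(n) as an (n_perm, n) index array.

    A fixed stream lets weight searches compare candidates on identical
    permutations, so candidate ranking is not corrupted by Monte-Carlo
    noise.
    """
    rng = np.random.default_rng(seed)
    return np.argsort(rng.random((n_perm, n)), axis=1)


def q_for_permutations(X, Y, perms: np.ndarray) -> tuple[float, np.ndarray]:
    """Observed Q and the vector of Q values under each permutation of Y."""
    X, Y = _validate(X, Y)
    n, m = X.shape
    mu = Y.mean()
    mu2 = mu * (1.0 - mu)
    scale = 1.0 / (m * mu2)
    z = Y - mu
    q_obs = float((X.T @ z) @ (X.T @ z)) * scale
    Z = z[perms]                       # (n_perm, n): permuted residuals
    V = Z @ X                          # (n_perm, m)
    q_perm = np.einsum("ij,ij->i", V, V) * scale
    return q_obs, q_perm


def permutation_p_value(X, Y, n_perm: int = 10_000, seed=None) -> GlobalTestResult:
    """Monte-Carlo permutation p-value for the global test.

    p = #{b : Q(X, permute_b(Y)) >= Q_obs} / n_perm.  Deterministic given
    ``seed`` (an int, SeedSequence or Generator).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    perms = make_permutation_stream(X.shape[0], n_perm, seed)
    q_obs, q_perm = q_for_permutations(X, Y, perms)
    Yf = np.asarray(Y, dtype=float)
    mu = Yf.mean()
    return GlobalTestResult(
        q_observed=q_obs,
        p_value=count_at_least(q_perm, q_obs) / n_perm,
        n_permutations=n_perm,
        mu=float(mu),
        mu2=float(mu * (1 - mu)),
        seed=seed if isinstance(seed, int) else None,
    )


def exact_permutation_p_value(X, Y) -> float:
    """Exact p-value by enumerating all distinct arrangements of Y.

    Q depends on Y only through the positions of the ones, so the
    permutation distribution has C(n, n1) atoms, each equally likely.
    Refuses n > 10.  The observed arrangement is always counted, so
    p >= 1 / C(n, n1).
    """
    X, Yf = _validate(X, Y)
    n, m = X.shape
    if n > _EXACT_MAX_N:
        raise ValueError(f"exact enumeration limited to n <= {_EXACT_MAX_N}")
    n1 = int(Yf.sum())
    mu = Yf.mean()
    mu2 = mu * (1.0 - mu)
    scale = 1.0 / (m * mu2)
    q_obs = compute_Q(X, Yf.astype(int))
    total = int(comb(n, n1, exact=True))
    hits = 0
    tol = _TIE_RTOL * (1.0 + abs(q_obs))
    y = np.empty(n)
    for ones in combinations(range(n), n1):
        y.fill(0.0)
        y[list(ones)] = 1.0
        v = X.T @ (y - mu)
        if float(v @ v) * scale >= q_obs - tol:
            hits += 1
    return hits / total
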