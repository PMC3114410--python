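"""Gene-weighting schemes for pathway matrices.

Two closed-form schemes derive a per-gene weight vector from differential
expression:

* ``absT`` — weight proportional to the absolute two-sample t statistic of
  each gene (pooled-variance form by default), normalized to sum to 1
  within the pathway: the most differentially expressed gene gets the
  largest weight.
* ``Qdiff`` — weight proportional to the leave-one-gene-out change
  |Q - Q(-j)| of the global-test statistic, normalized to sum to 1: a
  gene whose removal moves Q a lot is deemed most relevant.

Two random-search schemes instead minimize a pluggable objective (the
pathway's permutation p-value, or its random-forest OOB error):

* ``RWV`` — per-gene weight vector, m uniform draws in [lo, hi] followed
  by a resample of m of them with replacement (the two-step draw is kept
  literally; ``simple_draw`` collapses it to a single draw).
* ``RWM`` — per-cell n x m weight matrix of uniform draws, applied
  elementwise, giving the search n*m degrees of freedom.

Both searches start from uniform weights, so the best objective can never
exceed the uniform one, and they are deterministic given a seed.  Because
the global-test p-value is invariant to any uniform rescaling of X, only
the relative pattern of a weight vector matters to that objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .global_test import compute_Q, count_at_least, make_permutation_stream

logger = logging.getLogger("pathweight")

__all__ = [
    "WeightSpec",
    "WeightSearchResult",
    "abs_t_weights",
    "qdiff_weights",
    "rwv_search",
    "rwm_search",
    "apply_weights",
    "global_test_objective",
    "uniform_weights",
    "write_weights_tsv",
]

DEFAULT_RANGE = (0.1, 1.0)   # the pre-defined draw range for RWV/RWM
DEFAULT_COUNT = 25_000       # search iterations; tests use far smaller counts


@dataclass
class WeightSpec:
    """A per-gene weight vector or per-cell weight matrix for one pathway."""

    kind: str  # "vector" | "matrix"
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.kind not in ("vector", "matrix"):
            raise ValueError(f"unknown weight kind {self.kind!r}")
        if self.kind == "vector" and self.weights.ndim != 1:
            raise ValueError("vector weights must be 1-D")
        if self.kind == "matrix" and self.weights.ndim != 2:
            raise ValueError("matrix weights must be 2-D")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")


@dataclass
class WeightSearchResult:
    best_weights: WeightSpec
    best_objective: float
    initial_objective: float
    iterations_run: int
    seed: int | None
    objective_kind: str
    trace: np.ndarray | None = field(default=None, repr=False)


def apply_weights(X, spec: WeightSpec) -> np.ndarray:
    """Weighted matrix wX: column scaling (vector) or elementwise (matrix)."""
    X = np.asarray(X, dtype=float)
    if spec.kind == "vector":
        if spec.weights.shape != (X.shape[1],):
            raise ValueError(
                f"weight vector length {spec.weights.shape[0]} for {X.shape[1]} genes"
            )
        return X * spec.weights
    if spec.weights.shape != X.shape:
        raise ValueError(f"weight matrix {spec.weights.shape} for X {X.shape}")
    return X * spec.weights


def uniform_weights(m: int) -> WeightSpec:
    return WeightSpec("vector", np.ones(m))


def _split_classes(X, Y):
    Y = np.asarray(Y)
    return X[Y == 0], X[Y == 1]


def abs_t_weights(X, Y, welch: bool = False) -> WeightSpec:
    """|T|-proportional weights, normalized to sum to 1.

    T is the classical pooled-variance two-sample t statistic per gene
    (Welch's form behind the ``welch`` flag).  A gene with zero
    within-class variance but a nonzero mean difference would have
    infinite |T|; it is capped at the largest finite |T| in the pathway
    (or 1 if none exists) so the normalization stays defined.  If every
    |T| is zero the scheme falls back to uniform 1/m with a warning.
    """
    X = np.asarray(X, dtype=float)
    X0, X1 = _split_classes(X, Y)
    n0, n1 = len(X0), len(X1)
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs >= 2 samples to estimate variance")
    diff = X1.mean(axis=0) - X0.mean(axis=0)
    v0 = X0.var(axis=0, ddof=1)
    v1 = X1.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se = np.sqrt(v0 / n0 + v1 / n1)
        else:
            sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
            se = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
        t = np.abs(diff / se)
    t[np.isnan(t)] = 0.0  # zero variance and zero mean difference
    if np.isinf(t).any():
        finite = t[np.isfinite(t)]
        cap = finite.max() if finite.size and finite.max() > 0 else 1.0
        logger.warning("capping %d infinite |T| value(s) at %.6g",
                       int(np.isinf(t).sum()), cap)
        t[np.isinf(t)] = cap
    total = t.sum()
    if total == 0.0:
        logger.warning("all |T| zero; falling back to uniform weights")
        return WeightSpec("vector", np.full(X.shape[1], 1.0 / X.shape[1]))
    return WeightSpec("vector", t / total)


def qdiff_weights(X, Y) -> WeightSpec:
    """Leave-one-gene-out |Q - Q(-j)| weights, normalized to sum to 1.

    For m = 1 the leave-one-out statistic is undefined and the single gene
    receives weight 1.  If every difference is zero (e.g. duplicated
    columns of an all-equal matrix) the scheme falls back to uniform.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if m == 1:
        return WeightSpec("vector", np.array([1.0]))
    q_full = compute_Q(X, Y)
    diffs = np.empty(m)
    for j in range(m):
        q_minus = compute_Q(np.delete(X, j, axis=1), Y)
        diffs[j] = abs(q_full - q_minus)
    total = diffs.sum()
    if total == 0.0:
        logger.warning("all |Q - Q(-j)| zero; falling back to uniform weights")
        return WeightSpec("vector", np.full(m, 1.0 / m))
    return WeightSpec("vector", diffs / total)


# ---------------------------------------------------------------------------
# random-search schemes
# ---------------------------------------------------------------------------

def global_test_objective(Y, n_perm: int, seed):
    """Objective F(wX) = permutation p-value of the global test.

    The permutation stream is drawn once and reused for every candidate,
    so two candidates are always compared on identical permutations.
    Returns (p_value, -Q_obs); the -Q_obs term breaks exact p-value ties
    in favour of the larger observed statistic.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.min() == Y.max():
        raise ValueError("both classes must be present")
    perms = make_permutation_stream(len(Y), n_perm, seed)
    mu = Y.mean()
    mu2 = mu * (1.0 - mu)
    z = Y - mu
    Z = z[perms]  # permuted residuals depend only on Y: hoisted out of the loop

    def objective(Xw) -> tuple[float, float]:
        Xw = np.asarray(Xw, dtype=float)
        scale = 1.0 / (Xw.shape[1] * mu2)
        v = Xw.T @ z
        q_obs = float(v @ v) * scale
        V = Z @ Xw
        q_perm = np.einsum("ij,ij->i", V, V) * scale
        return count_at_least(q_perm, q_obs) / n_perm, -q_obs

    objective.kind = "global_test_p"
    return objective


def _as_pair(value) -> tuple[float, float]:
    if isinstance(value, tuple):
        return value
    return float(value), 0.0


def _random_search(X, Y, count, range_lo, range_hi, objective, seed,
                   draw, kind: str, record_trace: bool) -> WeightSearchResult:
    X = np.asarray(X, dtype=float)
    if count < 0:
        raise ValueError("count must be >= 0")
    if not (0 < range_lo <= range_hi):
        raise ValueError(f"invalid weight range [{range_lo}, {range_hi}]")
    rng = np.random.default_rng(seed)
    best_spec = uniform_weights(X.shape[1]) if kind == "vector" else WeightSpec(
        "matrix", np.ones_like(X))
    best = _as_pair(objective(X))
    initial = best[0]
    trace = np.empty(count + 1) if record_trace else None
    if record_trace:
        trace[0] = initial
    for i in range(count):
        w = draw(rng)
        cand = _as_pair(objective(apply_weights(X, WeightSpec(kind, w))))
        if cand < best:  # lexicographic: p first, then larger Q (stored as -Q)
            best = cand
            best_spec = WeightSpec(kind, w)
        if record_trace:
            trace[i + 1] = best[0]
    return WeightSearchResult(
        best_weights=best_spec,
        best_objective=best[0],
        initial_objective=initial,
        iterations_run=count,
        seed=seed if isinstance(seed, int) else None,
        objective_kind=getattr(objective, "kind", "custom"),
        trace=trace,
    )


def rwv_search(X, Y, count: int = DEFAULT_COUNT,
               range_lo: float = DEFAULT_RANGE[0],
               range_hi: float = DEFAULT_RANGE[1],
               objective=None, seed=None, simple_draw: bool = False,
               record_trace: bool = False) -> WeightSearchResult:
    """Random-weight-vector search: per-gene weights minimizing the objective.

    Each candidate draws m values uniformly in [range_lo, range_hi], then
    picks m of them with replacement — the literal two-step draw — unless
    ``simple_draw`` is set.  ``objective`` defaults to the global-test
    p-value at 10,000 permutations on a stream derived from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    if objective is None:
        obj_ss, search_ss = np.random.SeedSequence(seed).spawn(2)
        objective = global_test_objective(Y, 10_000, obj_ss)
        seed_for_draws = search_ss
    else:
        seed_for_draws = seed

    def draw(rng):
        base = rng.uniform(range_lo, range_hi, size=m)
        if simple_draw:
            return base
        return base[rng.integers(0, m, size=m)]

    res = _random_search(X, Y, count, range_lo, range_hi, objective,
                         seed_for_draws, draw, "vector", record_trace)
    if isinstance(seed, int):
        res.seed = seed
    return res


def rwm_search(X, Y, count: int = DEFAULT_COUNT,
               range_lo: float = DEFAULT_RANGE[0],
               range_hi: float = DEFAULT_RANGE[1],
               objective=None, seed=None,
               record_trace: bool = False) -> WeightSearchResult:
    """Random-weight-matrix search: per-cell n x m weights, elementwise.

    Identical to :func:`rwv_search` except each candidate is a full n x m
    matrix of uniform draws, so every sample of a gene may be weighted
    differently — the extra degrees of freedom are why this scheme can
    reach lower objectives than the vector search.
    """
    X = np.asarray(X, dtype=float)
    shape = X.shape
    if objective is None:
        obj_ss, search_ss = np.random.SeedSequence(seed).spawn(2)
        objective = global_test_objective(Y, 10_000, obj_ss)
        seed_for_draws = search_ss
    else:
        seed_for_draws = seed

    def draw(rng):
        return rng.uniform(range_lo, range_hi, size=shape)

    res = _random_search(X, Y, count, range_lo, range_hi, objective,
                         seed_for_draws, draw, "matrix", record_trace)
    if isinstance(seed, int):
        res.seed = seed
    return res


def write_weights_tsv(spec: WeightSpec, path, gene_ids, sample_ids=None) -> None:
    """Serialize weights: ``gene_id<TAB>weight`` rows for vectors, a
    sample x gene table with headers for matrices."""
    if spec.kind == "vector":
        pd.Series(spec.weights, index=gene_ids, name="weight").to_csv(
            path, sep="\t", index_label="gene_id", float_format="%.17g")
    else:
        pd.DataFrame(spec.weights, index=sample_ids, columns=gene_ids).to_csv(
            path, sep="\t", index_label="sample_id", float_format="%.17g")
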