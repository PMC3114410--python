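"""Random-forest out-of-bag error as a pathway score and search objective.

A bagged classification forest is grown on the pathway matrix; each
sample is scored by the majority vote of the trees for which it was
out-of-bag (roughly one third of trees), and the OOB error is the
fraction misclassified.  Samples that were never OOB — possible at very
small tree counts — are excluded from the denominator and counted in the
result.

Only the per-cell (RWM) weighting scheme is meaningful here: a per-gene
weight rescales a column monotonically, which leaves every tree's split
structure attainable and the OOB error unchanged, so vector schemes are
rejected with :class:`UnsupportedCombinationError`.

Forest conventions follow the classical randomForest lineage: mtry =
floor(sqrt(m)) candidate features per split, unlimited depth, bootstrap
sample size n.  Default 1,000 trees for interactive use; the 50,000-tree
setting is available behind ``full_fidelity``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .weighting import WeightSearchResult, rwm_search

__all__ = [
    "OOBResult",
    "UnsupportedCombinationError",
    "oob_error",
    "oob_objective",
    "rwm_search_oob",
    "check_scheme_method",
    "DEFAULT_N_TREES",
    "FIDELITY_N_TREES",
]

DEFAULT_N_TREES = 1_000
FIDELITY_N_TREES = 50_000

VECTOR_SCHEMES = ("absT", "Qdiff", "RWV")


class UnsupportedCombinationError(ValueError):
    """Vector-weight schemes do not change RF out-of-bag error.

    absT, Qdiff and RWV apply one weight across all samples of a gene;
    such a monotone column rescaling cannot change which splits a tree can
    make, so the OOB outcome is unchanged and scoring these schemes under
    the random forest is meaningless.
    """


def check_scheme_method(scheme: str, method: str) -> None:
    """Raise if ``scheme`` cannot be scored under ``method``."""
    if method == "random_forest" and scheme in VECTOR_SCHEMES:
        raise UnsupportedCombinationError(
            f"scheme {scheme!r} applies the same weight across all samples of "
            "a gene, which does not change the out-of-bag error; use 'uniform' "
            "or 'RWM' with the random forest"
        )


@dataclass
class OOBResult:
    oob_error: float
    n_trees: int
    seed: int | None
    n_never_oob: int = 0


def _validate(X, Y):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    if Y.min() == Y.max():
        raise ValueError("both classes must be present")
    return X, Y.astype(int)


def oob_error(X, Y, n_trees: int = DEFAULT_N_TREES, seed=None) -> OOBResult:
    """Out-of-bag misclassification rate of a bagged forest on (X, Y)."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X, Y = _validate(X, Y)
    rs = seed if isinstance(seed, int) else np.random.default_rng(seed).integers(2**31)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=int(rs),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # at tiny tree counts sklearn warns that some samples lack OOB votes
        warnings.simplefilter("ignore", UserWarning)
        forest.fit(X, Y)
    votes = forest.oob_decision_function_
    has_votes = ~np.isnan(votes).any(axis=1) & (votes.sum(axis=1) > 0)
    n_never = int(np.count_nonzero(~has_votes))
    if n_never == len(Y):
        raise ValueError("no sample received an out-of-bag vote; raise n_trees")
    pred = forest.classes_[votes[has_votes].argmax(axis=1)]
    err = float(np.mean(pred != Y[has_votes]))
    return OOBResult(oob_error=err, n_trees=n_trees, seed=int(rs),
                     n_never_oob=n_never)


def oob_objective(Y, n_trees: int, seed):
    """Objective F(wX) = OOB error with a fixed tree seed.

    Every candidate forest uses the same random state, so the comparison
    between candidates isolates the effect of the weights.
    """
    tree_seed = int(np.random.default_rng(seed).integers(2**31))

    def objective(Xw) -> float:
        return oob_error(Xw, Y, n_trees=n_trees, seed=tree_seed).oob_error

    objective.kind = "oob_error"
    return objective


def rwm_search_oob(X, Y, count: int, range_lo: float = 0.1,
                   range_hi: float = 1.0, n_trees: int = DEFAULT_N_TREES,
                   seed=None, record_trace: bool = False) -> WeightSearchResult:
    """RWM search minimizing the forest OOB error for one pathway."""
    obj_ss, search_ss = np.random.SeedSequence(seed).spawn(2)
    objective = oob_objective(Y, n_trees, obj_ss)
    res = rwm_search(X, Y, count=count, range_lo=range_lo, range_hi=range_hi,
                     objective=objective, seed=search_ss,
                     record_trace=record_trace)
    if isinstance(seed, int):
        res.seed = seed
    return res
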