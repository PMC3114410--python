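"""Synthetic pathway-expression generator.

One pathway is modeled as a multivariate normal over its m genes: a mean
vector and a full covariance matrix (which fixes the correlation
structure), estimated from data or specified directly.  A simulated
dataset draws the normal group from MVN(mean, cov) and the disease group
from MVN(mean + shift, cov); with shift = 0 the two groups are draws from
one model and every pathway is null — the label-assignment design used
for calibration studies.  Groups are balanced when n is even.

:func:`make_synthetic_study` builds a full screening fixture — a gene
universe, a pathway collection, background-noise expression, and a set of
"informative" pathways carrying a planted mean shift on half of their
member genes — together with a ground-truth table, so every downstream
screen is testable end to end without external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import ExpressionDataset, PathwayCollection, PathwayEntry, PathwayMatrix

logger = logging.getLogger("pathweight")

__all__ = [
    "PathwayModel",
    "SyntheticStudy",
    "estimate_moments",
    "simulate_pathway",
    "make_synthetic_study",
]

_PSD_TOL = 1e-10


@dataclass
class PathwayModel:
    """MVN model of one pathway: mean, covariance, disease-group mean shift."""

    mean: np.ndarray
    covariance: np.ndarray
    shift: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        m = self.mean.shape[0]
        if self.covariance.shape != (m, m):
            raise ValueError("covariance shape does not match mean length")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        eigmin = float(np.linalg.eigvalsh(self.covariance).min())
        if eigmin < -_PSD_TOL * max(1.0, float(np.abs(self.covariance).max())):
            raise ValueError(f"covariance not PSD (min eigenvalue {eigmin:.3g})")
        if self.shift is None:
            self.shift = np.zeros(m)
        else:
            self.shift = np.asarray(self.shift, dtype=float)
            if self.shift.shape != (m,):
                raise ValueError("shift length does not match mean length")

    @property
    def n_genes(self) -> int:
        return self.mean.shape[0]


def estimate_moments(X) -> PathwayModel:
    """Sample mean and covariance (denominator n-1) of a pathway matrix.

    Estimated covariances can carry tiny negative eigenvalues from
    round-off; these are clipped at zero with a logged adjustment so the
    model is always simulable.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x m matrix with n >= 2")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1])
    cov = (cov + cov.T) / 2.0
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval.min() < 0:
        logger.info("clipping %d negative eigenvalue(s) (min %.3g) to 0",
                    int((eigval < 0).sum()), float(eigval.min()))
        cov = (eigvec * np.clip(eigval, 0, None)) @ eigvec.T
        cov = (cov + cov.T) / 2.0
    return PathwayModel(mean=mean, covariance=cov)


def simulate_pathway(model: PathwayModel, n_samples: int, seed=None,
                     gene_ids: list[str] | None = None) -> PathwayMatrix:
    """Draw a two-group pathway matrix from the model.

    The first half of the samples is the normal group (label 0, mean
    ``model.mean``); the second half is the disease group (label 1, mean
    ``model.mean + model.shift``).  Odd n gives groups differing by one
    with a warning.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_samples % 2:
        logger.warning("odd n_samples=%d: groups of %d and %d",
                       n_samples, n_samples // 2, n_samples - n_samples // 2)
    rng = np.random.default_rng(seed)
    n0 = n_samples // 2
    n1 = n_samples - n0
    X0 = rng.multivariate_normal(model.mean, model.covariance, size=n0,
                                 method="svd")
    X1 = rng.multivariate_normal(model.mean + model.shift, model.covariance,
                                 size=n1, method="svd")
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    if gene_ids is None:
        gene_ids = [f"G{j + 1}" for j in range(model.n_genes)]
    return PathwayMatrix(values=np.vstack([X0, X1]), gene_ids=gene_ids,
                         labels=labels)


@dataclass
class SyntheticStudy:
    dataset: ExpressionDataset
    pathways: PathwayCollection
    truth: pd.DataFrame = field(repr=False)


def make_synthetic_study(
    n_genes: int = 2000,
    n_pathways: int = 20,
    pathway_size_range: tuple[int, int] = (10, 30),
    n_samples: int = 50,
    n_informative_pathways: int = 3,
    shift_size: float = 2.0,
    informative_fraction: float = 0.5,
    seed=None,
) -> SyntheticStudy:
    """Generate a full synthetic screening study with ground truth.

    Background expression is i.i.d. standard normal for every gene.  Gene
    sets are sampled without replacement within a pathway (overlap across
    pathways is allowed, as in real collections).  The first
    ``n_informative_pathways`` pathways are informative: a round(fraction
    * size) subset of their member genes receives a ``shift_size`` mean
    shift in the disease group.  Shifted genes are chosen among members
    private to their pathway whenever possible, so pathways outside the
    truth table really are null; only if a pathway has too few private
    genes does the shift spill onto shared members (logged).  Returns the
    dataset (labels attached), the pathway collection, and a truth table
    with one row per informative pathway listing its shifted genes.
    """
    lo, hi = pathway_size_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid pathway size range")
    if hi > n_genes:
        raise ValueError("pathway size exceeds the gene universe")
    if n_informative_pathways > n_pathways:
        raise ValueError("more informative pathways than pathways")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{j + 1:05d}" for j in range(n_genes)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    n0 = n_samples // 2
    labels = np.concatenate(
        [np.zeros(n0, dtype=int), np.ones(n_samples - n0, dtype=int)])
    values = rng.standard_normal((n_samples, n_genes))

    entries = []
    member_sets = []
    for k in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        member_sets.append(members)
        entries.append(PathwayEntry(f"PW{k + 1:03d}",
                                    f"synthetic pathway {k + 1}",
                                    [gene_ids[g] for g in members]))

    membership_count = np.zeros(n_genes, dtype=int)
    for members in member_sets:
        membership_count[members] += 1

    truth_rows = []
    for k in range(n_informative_pathways):
        members = member_sets[k]
        n_shift = max(1, round(informative_fraction * len(members)))
        private = members[membership_count[members] == 1]
        if len(private) >= n_shift:
            pool = private
        else:
            logger.warning(
                "pathway %s: only %d private genes for %d planted shifts; "
                "shift will touch shared members", entries[k].pathway_id,
                len(private), n_shift)
            pool = members
        shifted = rng.choice(pool, size=n_shift, replace=False)
        values[np.ix_(labels == 1, shifted)] += shift_size
        truth_rows.append({
            "pathway_id": entries[k].pathway_id,
            "n_genes": len(members),
            "shifted_genes": ",".join(gene_ids[g] for g in sorted(shifted)),
            "shift_size": shift_size,
        })
    truth = pd.DataFrame(truth_rows,
                         columns=["pathway_id", "n_genes", "shifted_genes",
                                  "shift_size"])
    dataset = ExpressionDataset(values=values, gene_ids=gene_ids,
                                sample_ids=sample_ids, labels=labels)
    return SyntheticStudy(dataset=dataset, pathways=PathwayCollection(entries),
                          truth=truth)
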