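"""Leave-one-out prediction rates of selected pathways.

Each pathway's expression submatrix is evaluated with four standard
classifiers — LDA, linear-kernel SVM, polynomial-kernel SVM and k-nearest
neighbours — under leave-one-out cross-validation: every sample is
predicted once by a model trained on the others, and the rate is the
fraction predicted correctly.  Per-(classifier, scheme) cell values are
the unweighted mean of per-pathway rates.

Hyperparameters are conventions, all overridable: KNN k=3, polynomial
degree 3, SVM C=1, LDA with its default SVD solver (robust to singular
pooled covariance).  Features can optionally be standardized inside each
training fold.

Note that a per-gene (vector) weight rescales columns uniformly across
samples, which cannot change what a scale-invariant classifier learns;
scale-sensitive classifiers (KNN, SVM) may still react to column scaling.
Only a per-cell (matrix) weight genuinely alters single-gene information,
so prediction evaluation mainly discriminates the RWM scheme from the
rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .core_data import ExpressionDataset, PathwayCollection, extract_pathway_matrix
from .weighting import WeightSpec, apply_weights

logger = logging.getLogger("pathweight")

__all__ = [
    "CLASSIFIERS",
    "PredictionReport",
    "make_classifier",
    "loocv_rate",
    "evaluate_topk",
]

CLASSIFIERS = ("LDA", "SVM_linear", "SVM_poly", "KNN")

DEFAULT_PARAMS = {"knn_k": 3, "svm_C": 1.0, "poly_degree": 3}


@dataclass
class PredictionReport:
    rows: pd.DataFrame = field(repr=False)         # classifier, scheme, mean_rate
    per_pathway: pd.DataFrame = field(repr=False)  # pathway_id, classifier, scheme, rate


def make_classifier(name: str, params: dict | None = None):
    p = {**DEFAULT_PARAMS, **(params or {})}
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "SVM_linear":
        return SVC(kernel="linear", C=p["svm_C"])
    if name == "SVM_poly":
        return SVC(kernel="poly", degree=p["poly_degree"], C=p["svm_C"])
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=p["knn_k"])
    raise ValueError(f"unknown classifier {name!r}")


def loocv_rate(X, Y, classifier: str, classifier_params: dict | None = None,
               standardize: bool = False) -> float:
    """Fraction of samples correctly predicted under leave-one-out CV.

    A fold whose training labels are single-class, or whose training
    features carry no variation at all, scores the held-out sample by the
    training-fold majority class (ties to class 0), with a log message.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=int)
    n = len(Y)
    if n < 3:
        raise ValueError("LOOCV needs n >= 3")
    if Y.min() == Y.max():
        raise ValueError("both classes must be present")
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], Y[mask]
        x_te = X[i:i + 1]
        if standardize:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0)
            sd[sd == 0] = 1.0
            X_tr = (X_tr - mu) / sd
            x_te = (x_te - mu) / sd
        if y_tr.min() == y_tr.max() or np.all(X_tr == X_tr[0]):
            # degenerate fold: majority-class fallback
            pred = int(np.bincount(y_tr, minlength=2).argmax())
            logger.debug("fold %d degenerate; majority fallback -> %d", i, pred)
        else:
            clf = make_classifier(classifier, classifier_params)
            clf.fit(X_tr, y_tr)
            pred = int(clf.predict(x_te)[0])
        correct += int(pred == Y[i])
    return correct / n


def evaluate_topk(dataset: ExpressionDataset, pathways: PathwayCollection,
                  top_rows: pd.DataFrame, scheme: str = "uniform",
                  weight_specs: dict[str, WeightSpec] | None = None,
                  classifiers=CLASSIFIERS,
                  classifier_params: dict | None = None,
                  standardize: bool = False) -> PredictionReport:
    """LOOCV prediction rates for the pathways of one top-k selection.

    ``weight_specs`` maps pathway_id to the weights the scheme produced
    for that pathway (None or a missing id means unweighted expression,
    the uniform case); the weighted matrix is what the classifiers see.
    Cell means are unweighted averages of per-pathway rates.
    """
    if top_rows.empty:
        raise ValueError("empty top-k selection")
    weight_specs = weight_specs or {}
    per_rows = []
    for pid in top_rows["pathway_id"]:
        pm = extract_pathway_matrix(dataset, pathways[pid])
        X = pm.values
        spec = weight_specs.get(pid)
        if spec is not None:
            X = apply_weights(X, spec)
        for clf in classifiers:
            rate = loocv_rate(X, pm.labels, clf, classifier_params,
                              standardize=standardize)
            per_rows.append({"pathway_id": pid, "classifier": clf,
                             "scheme": scheme, "rate": rate})
    per_pathway = pd.DataFrame(per_rows)
    rows = (per_pathway.groupby(["classifier", "scheme"], sort=False)["rate"]
            .mean().reset_index().rename(columns={"rate": "mean_rate"}))
    return PredictionReport(rows=rows, per_pathway=per_pathway)
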