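"""Chemometric baseline: exploratory PCA/HCA and a validated PLS-DA model.

PLS-DA regresses a 0/1 class-membership matrix Y on the spectral block X
(NIPALS partial least squares), classifying each sample into the class
with the largest predicted response.  Model quality is reported the way
chemometric software prints it:

* per-class one-vs-rest sensitivity SEN = TP/(TP+FN), specificity
  SPE = TN/(TN+FP), accuracy ACC = (TP+TN)/(TP+TN+FP+FN), and ROC/AUC;
* RMSEE (root mean square error of estimation, on the fitted Y-block)
  and RMSECV (its k-fold cross-validated counterpart), with R² and Q²
  the corresponding 1 − SS_res/SS_tot;
* a label-permutation test whose R²/Q² intercepts at zero
  label-correlation diagnose overfitting.

The X-block is mean-centered only by default; unit-variance scaling is
behind a flag.  Cross-validation uses venetian-blind fold assignment
after class-stratified ordering, so folds are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _PCA
from sklearn.metrics import roc_auc_score, roc_curve

from .datasets import SpectrumSet, class_means

__all__ = [
    "PLSDAClassifier", "ClassMetrics", "ValidationReport",
    "PermutationResult", "pca", "hca", "fit_plsda", "classify",
    "confusion_metrics", "roc_auc", "validate", "permutation_test",
    "select_latent_variables", "venetian_blind_folds", "class_metrics_table",
]


def _one_hot(y: np.ndarray, classes: Sequence) -> np.ndarray:
    return (np.asarray(y)[:, None] == np.asarray(classes)[None, :]).astype(float)


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """Partial least squares discriminant analysis.

    Y is one-hot class membership (1 = belongs to the class, 0 = does
    not); components are extracted sequentially to maximize X–Y
    covariance (NIPALS).  Prediction returns continuous Y-scores, with
    the hard label the argmax per row (ties resolve to the first class
    in sorted label order).

    Parameters
    ----------
    n_components : number of latent variables (LVs), ``1 ≤ LVs ≤
        min(n_samples − 1, n_features)``.
    scale : also scale X columns to unit variance (default: mean-center
        only).
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y)
        self.classes_ = np.array(sorted(pd.unique(y).tolist()))
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        cap = min(X.shape[0] - 1, X.shape[1])
        if not 1 <= self.n_components <= cap:
            raise ValueError(
                f"n_components must be in [1, {cap}] for X of shape {X.shape}")
        Y = _one_hot(y, self.classes_)
        self.pls_ = PLSRegression(n_components=self.n_components,
                                  scale=self.scale)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # y residual near-constant is fine
            self.pls_.fit(X, Y)
        self.x_weights_ = self.pls_.x_weights_
        self.x_loadings_ = self.pls_.x_loadings_
        self.y_loadings_ = self.pls_.y_loadings_
        self.x_mean_ = self.pls_._x_mean
        self.y_mean_ = self.pls_._y_mean
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Continuous predicted-Y scores, one column per class."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        return self.pls_.predict(X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def fit_plsda(X, labels, n_latent: int, scale: bool = False) -> PLSDAClassifier:
    """Functional wrapper over :class:`PLSDAClassifier`."""
    X = X.absorbance if isinstance(X, SpectrumSet) else X
    return PLSDAClassifier(n_components=n_latent, scale=scale).fit(X, labels)


def classify(model: PLSDAClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and continuous scores for ``X``."""
    scores = model.decision_function(X)
    return model.classes_[np.argmax(scores, axis=1)], scores


# -- metrics ---------------------------------------------------------------

@dataclass
class ClassMetrics:
    """One-vs-rest confusion counts and derived fractions for one class."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None

    @property
    def sen(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def spe(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)


def confusion_metrics(y_true, y_pred, cls) -> ClassMetrics:
    """SEN/SPE/ACC counts for ``cls`` against all other classes."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("truth and prediction lengths differ")
    pos_t, pos_p = y_true == cls, y_pred == cls
    return ClassMetrics(tp=int(np.sum(pos_t & pos_p)),
                        fp=int(np.sum(~pos_t & pos_p)),
                        tn=int(np.sum(~pos_t & ~pos_p)),
                        fn=int(np.sum(pos_t & ~pos_p)))


def roc_auc(truth, scores) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC points and area under the curve for binary truth vs scores.

    AUC equals the Mann–Whitney concordant-pair statistic (tied scores
    count half), so it is insensitive to monotone score transforms.
    """
    truth = np.asarray(truth).astype(bool)
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(truth, scores)
    return (fpr, tpr), float(roc_auc_score(truth, scores))


def class_metrics_table(y_true, y_pred, score_matrix: np.ndarray | None,
                        classes: Sequence) -> pd.DataFrame:
    """Per-class SEN/SPE/ACC (and AUC when scores are given)."""
    rows = []
    y_true = np.asarray(y_true)
    for k, cls in enumerate(classes):
        m = confusion_metrics(y_true, y_pred, cls)
        auc = np.nan
        if score_matrix is not None:
            truth = y_true == cls
            if truth.any() and not truth.all():
                auc = roc_auc(truth, np.asarray(score_matrix)[:, k])[1]
        rows.append({"class": cls, "tp": m.tp, "fp": m.fp, "tn": m.tn,
                     "fn": m.fn, "sen": m.sen, "spe": m.spe, "acc": m.acc,
                     "auc": auc})
    return pd.DataFrame(rows)


# -- cross-validated model diagnostics ------------------------------------

def venetian_blind_folds(y, folds: int) -> np.ndarray:
    """Deterministic fold labels: class-stratified ordering, then modulo
    assignment (venetian blinds)."""
    y = np.asarray(y)
    order = np.lexsort((np.arange(y.size), y.astype(str)))
    fold_of = np.empty(y.size, dtype=int)
    fold_of[order] = np.arange(y.size) % folds
    return fold_of


@dataclass
class ValidationReport:
    rmsee: float
    rmsecv: float
    r2: float
    q2: float
    n_components: int
    folds: int


def validate(X, y, n_components: int, folds: int = 7,
             scale: bool = False) -> ValidationReport:
    """RMSEE/R² on the fitted Y-block and RMSECV/Q² under k-fold CV.

    Errors are computed jointly across the whole one-hot Y-block (one
    scalar per model).  If a training partition would lose a class, the
    fold count is reduced with a warning until every partition sees all
    classes.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y)
    classes = np.array(sorted(pd.unique(y).tolist()))
    if classes.size < 2:
        raise ValueError("need at least two classes")
    sizes = {c: int(np.sum(y == c)) for c in classes}
    if min(sizes.values()) < 2:
        small = min(sizes, key=sizes.get)
        raise ValueError(f"class {small!r} needs >= 2 samples for "
                         f"cross-validation")
    Y = _one_hot(y, classes)

    model = PLSDAClassifier(n_components, scale).fit(X, y)
    resid = Y - model.decision_function(X)
    sstot = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    rmsee = float(np.sqrt(np.mean(resid ** 2)))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sstot

    fold_of = venetian_blind_folds(y, folds)
    while folds > 2 and any(
            np.unique(y[fold_of != f]).size < classes.size
            for f in range(folds)):
        folds -= 1
        warnings.warn(f"fold missing a class; refolding with {folds} folds")
        fold_of = venetian_blind_folds(y, folds)

    Yhat_cv = np.empty_like(Y)
    for f in range(folds):
        tr = fold_of != f
        ncomp = min(n_components, int(tr.sum()) - 1, X.shape[1])
        sub = PLSDAClassifier(ncomp, scale).fit(X[tr], y[tr])
        Yhat_cv[~tr] = sub.decision_function(X[~tr])
    resid_cv = Y - Yhat_cv
    rmsecv = float(np.sqrt(np.mean(resid_cv ** 2)))
    q2 = 1.0 - float(np.sum(resid_cv ** 2)) / sstot
    return ValidationReport(rmsee, rmsecv, r2, q2, n_components, folds)


@dataclass
class PermutationResult:
    """Label-permutation scatter and its regression intercepts.

    ``table`` has one row per model — the unpermuted reference at
    correlation 1 plus one per permutation — with columns
    ``correlation, r2, q2``.  Intercepts come from least-squares lines
    through all points (reference included), evaluated at correlation 0.
    """

    table: pd.DataFrame
    r2_intercept: float
    q2_intercept: float


def permutation_test(X, y, n_perm: int = 200, n_components: int = 2,
                     folds: int = 7, scale: bool = False,
                     seed: int = 0) -> PermutationResult:
    """Y-scrambling robustness test of the PLS-DA model."""
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    y = np.asarray(y)
    classes = np.array(sorted(pd.unique(y).tolist()))
    if classes.size < 2:
        raise ValueError("need at least two classes")
    Y0 = _one_hot(y, classes)
    ref = validate(X, y, n_components, folds, scale)
    rows = [{"correlation": 1.0, "r2": ref.r2, "q2": ref.q2}]
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_perm):
            perm = rng.permutation(y.size)
            yp = y[perm]
            corr = abs(float(np.corrcoef(Y0.ravel(),
                                         _one_hot(yp, classes).ravel())[0, 1]))
            rep = validate(X, yp, n_components, folds, scale)
            rows.append({"correlation": corr, "r2": rep.r2, "q2": rep.q2})
    table = pd.DataFrame(rows)
    r2_line = np.polyfit(table["correlation"], table["r2"], 1)
    q2_line = np.polyfit(table["correlation"], table["q2"], 1)
    return PermutationResult(table, float(r2_line[1]), float(q2_line[1]))


def select_latent_variables(X, y, max_lv: int = 15, folds: int = 7,
                            scale: bool = False, tol: float = 0.01) -> int:
    """LV count maximizing cross-validated Q².

    Ties go to the smallest count; Q² values within ``tol`` of the maximum
    count as tied, so extra components that buy no real predictive power
    are not selected (the usual parsimony rule for Q²-based selection).
    """
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[0]
    cap = min(max_lv, X.shape[1], n - int(np.ceil(n / folds)) - 1)
    cap = max(cap, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        q2s = [validate(X, y, lv, folds, scale).q2
               for lv in range(1, cap + 1)]
    best = max(q2s)
    return 1 + next(i for i, q in enumerate(q2s) if q >= best - tol)


# -- exploratory stage -----------------------------------------------------

def pca(X, n_components: int = 2):
    """Column-mean-centered PCA via SVD.

    Returns ``(scores, loadings, explained_variance_ratio)`` with scores
    (n × k), loadings (p × k) and non-increasing variance fractions.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 1 <= n_components <= min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("invalid n_components")
    p = _PCA(n_components=n_components, svd_solver="full").fit(X)
    return p.transform(X), p.components_.T, p.explained_variance_ratio_


def hca(X, labels, method: str = "ward"):
    """Agglomerative clustering of class-mean spectra.

    Returns ``(Z, classes)``: a scipy linkage matrix over the class means
    (merge heights non-decreasing for ward/single/complete/average) and
    the class order its leaves refer to.  Suitable for (circular)
    dendrogram rendering.
    """
    classes, means = class_means(X, labels)
    if len(classes) < 2:
        raise ValueError("HCA needs at least 2 classes")
    Z = _scipy_linkage(means, method=method)
    return Z, classes
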