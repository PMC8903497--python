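"""Nested leave-one-out classification with embedded feature selection.

Every data-dependent choice — training-fold standardization and feature
selection — is made inside each training fold, so the held-out subject
never influences the model that predicts it (auditable from the fold
logs).  Selectors: top-|Pearson| correlation with outcome, two-group
F-ratio (identical ranking for two classes, since F = t**2), and recursive
feature elimination with a linear SVM.  Classifiers: RBF-kernel SVM,
Gaussian naive Bayes, LDA, and k-nearest neighbors with k fixed from the
full sample size (floor of its square root).

Significance uses the permutation scheme of the source analysis: labels
are shuffled, but each fold's feature set stays FROZEN to the true-label
selection for that fold; only the classifier is refit.  A fully
re-selected variant is available behind a flag for methodological
comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.feature_selection import RFE
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import CohortLabels, FeatureId, FeatureTable

__all__ = [
    "SelectorSpec",
    "ClassifierSpec",
    "Metrics",
    "FoldResult",
    "CvRun",
    "PermutationNull",
    "select_pearson",
    "select_ftest",
    "select_rfe",
    "run_nested_loocv",
    "compute_metrics",
    "permutation_test",
    "run_grid",
]

SELECTOR_METHODS = ("pearson", "ftest", "rfe")
CLASSIFIER_KINDS = ("svm_rbf", "gaussian_nb", "lda", "knn")


@dataclass(frozen=True)
class SelectorSpec:
    method: str = "pearson"
    k_features: int = 20
    rfe_step: float = 0.1
    rfe_inner_folds: int = 3

    def __post_init__(self) -> None:
        if self.method not in SELECTOR_METHODS:
            raise ValueError(f"unknown selector {self.method!r}")
        if self.k_features < 1:
            raise ValueError("k_features must be >= 1")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "svm_rbf"
    knn_k: Optional[int] = None  # None -> floor(sqrt(total sample size))
    svm_c: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier {self.kind!r}")


@dataclass(frozen=True)
class Metrics:
    """Confusion-matrix summary; undefined ratios (0/0) are None."""

    accuracy: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "ppv": self.ppv,
                "npv": self.npv}


@dataclass
class FoldResult:
    subject_id: str
    y_true: int
    y_pred: int
    selected_idx: list[int]
    selected: list[FeatureId]


@dataclass
class CvRun:
    folds: list[FoldResult]
    metrics: Metrics
    selector: SelectorSpec
    classifier: ClassifierSpec
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def accuracy(self) -> float:
        return self.metrics.accuracy

    def to_dict(self) -> dict:
        return {
            "selector": self.selector.__dict__ | {},
            "classifier": self.classifier.__dict__ | {},
            "seed": self.seed,
            "metrics": self.metrics.as_dict(),
            "folds": [{"subject_id": f.subject_id, "y_true": f.y_true,
                       "y_pred": f.y_pred,
                       "selected": [str(s) for s in f.selected]}
                      for f in self.folds],
        }


@dataclass
class PermutationNull:
    null_accuracies: np.ndarray
    observed: float
    z: Optional[float]
    p_empirical: float
    n_permutations: int


# --------------------------------------------------------------------------
# selectors (index-based; rankings are deterministic with stable ties)


def _check_training_fold(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("a class is absent from the training fold")


def select_pearson(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Top-k features by |point-biserial correlation| with the outcome.

    Constant features get correlation 0; ties break by column order.
    """
    _check_training_fold(y)
    X = np.asarray(X, dtype=float)
    yc = y - y.mean()
    xc = X - X.mean(axis=0)
    ssx = np.einsum("ij,ij->j", xc, xc)
    ssy = float(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / np.sqrt(ssx * ssy)
    r[~np.isfinite(r)] = 0.0
    if k > X.shape[1]:
        warnings.warn(f"k={k} > {X.shape[1]} features; returning all")
        k = X.shape[1]
    order = np.argsort(-np.abs(r), kind="stable")
    return order[:k]


def select_ftest(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Top-k by the two-group F ratio of mean square variances.

    For two classes F = t**2, so the ranking coincides with |Pearson|.
    """
    _check_training_fold(y)
    X = np.asarray(X, dtype=float)
    groups = [X[y == g] for g in np.unique(y)]
    n = X.shape[0]
    grand = X.mean(axis=0)
    between = sum(g.shape[0] * (g.mean(axis=0) - grand) ** 2 for g in groups)
    within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    df_b, df_w = len(groups) - 1, n - len(groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (between / df_b) / (within / df_w)
    # 0/0 (constant feature) ranks last; x/0 (perfect separation) first
    f[np.isnan(f)] = 0.0
    if k > X.shape[1]:
        warnings.warn(f"k={k} > {X.shape[1]} features; returning all")
        k = X.shape[1]
    order = np.argsort(-f, kind="stable")
    return order[:k]


def select_rfe(X: np.ndarray, y: np.ndarray, k: int,
               step: float = 0.1, inner_folds: int = 3,
               seed: int = 0) -> np.ndarray:
    """Recursive feature elimination with a linear SVM.

    Features are eliminated by weight magnitude in steps of ``step`` (a
    fraction per iteration); the retained size (<= k) is chosen by inner
    stratified cross-validation over the RFE ranking.
    """
    _check_training_fold(y)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    k = min(k, p)
    est = SVC(kernel="linear", C=1.0)
    rfe = RFE(est, n_features_to_select=1, step=step)
    rfe.fit(X, y)
    ranking = np.argsort(rfe.ranking_, kind="stable")  # best first

    class_min = np.bincount(y).min()
    folds = min(inner_folds, class_min)
    if folds < 2:
        return np.sort(ranking[:k])
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sizes = np.arange(1, k + 1)
    scores = np.zeros(sizes.size)
    for tr, te in cv.split(X, y):
        for i, s in enumerate(sizes):
            cols = ranking[:s]
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(X[np.ix_(tr, cols)], y[tr])
            scores[i] += clf.score(X[np.ix_(te, cols)], y[te])
    # ties prefer the larger size: at equal inner-CV accuracy keep the
    # full selection budget rather than collapsing to one feature
    best = sizes[sizes.size - 1 - int(np.argmax(scores[::-1]))]
    return np.sort(ranking[:best])


def _select(spec: SelectorSpec, X: np.ndarray, y: np.ndarray,
            seed: int) -> np.ndarray:
    if spec.method == "pearson":
        return select_pearson(X, y, spec.k_features)
    if spec.method == "ftest":
        return select_ftest(X, y, spec.k_features)
    return select_rfe(X, y, spec.k_features, step=spec.rfe_step,
                      inner_folds=spec.rfe_inner_folds, seed=seed)


# --------------------------------------------------------------------------
# metrics


def compute_metrics(y_pred: Sequence[int], y_true: Sequence[int],
                    positive: int = 1) -> Metrics:
    """The five confusion-matrix metrics; 0/0 ratios are reported missing."""
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if y_pred.shape != y_true.shape or y_pred.size == 0:
        raise ValueError("prediction/label length mismatch")
    tp = int(np.sum((y_pred == positive) & (y_true == positive)))
    tn = int(np.sum((y_pred != positive) & (y_true != positive)))
    fp = int(np.sum((y_pred == positive) & (y_true != positive)))
    fn = int(np.sum((y_pred != positive) & (y_true == positive)))

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return Metrics(accuracy=(tp + tn) / y_true.size,
                   sensitivity=ratio(tp, tp + fn),
                   specificity=ratio(tn, tn + fp),
                   ppv=ratio(tp, tp + fp),
                   npv=ratio(tn, tn + fn))


# --------------------------------------------------------------------------
# nested LOOCV


def _make_classifier(spec: ClassifierSpec, n_total: int):
    if spec.kind == "svm_rbf":
        # gamma='scale' = 1/(p * var(X)): the toolkit default kernel width
        return SVC(kernel="rbf", C=spec.svm_c, gamma="scale")
    if spec.kind == "gaussian_nb":
        return GaussianNB()
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis()
    k = spec.knn_k if spec.knn_k is not None else int(math.isqrt(n_total))
    return KNeighborsClassifier(n_neighbors=k)


def _fold_design(table: FeatureTable, labels: CohortLabels,
                 selector: SelectorSpec, standardize: bool, seed: int):
    """Per-fold standardized matrices and embedded selections."""
    X = table.values
    y = labels.y(table.subject_ids)
    n = X.shape[0]
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need at least two subjects per class")
    folds = []
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        y_tr = y[tr]
        _check_training_fold(y_tr)
        if standardize:
            scaler = StandardScaler().fit(X[tr])
            X_tr = scaler.transform(X[tr])
            X_te = scaler.transform(X[i:i + 1])
        else:
            X_tr, X_te = X[tr], X[i:i + 1]
        sel = _select(selector, X_tr, y_tr, seed)
        folds.append((i, tr, X_tr[:, sel], X_te[:, sel], sel))
    return X, y, folds


def run_nested_loocv(table: FeatureTable, labels: CohortLabels,
                     selector: SelectorSpec = SelectorSpec(),
                     classifier: ClassifierSpec = ClassifierSpec(),
                     seed: int = 0) -> CvRun:
    """Leave-one-out CV with selection embedded in every training fold."""
    _, y, folds = _fold_design(table, labels, selector,
                               classifier.standardize, seed)
    n = len(y)
    results = []
    for i, tr, X_tr, X_te, sel in folds:
        clf = _make_classifier(classifier, n)
        clf.fit(X_tr, y[tr])
        pred = int(clf.predict(X_te)[0])
        results.append(FoldResult(
            subject_id=table.subject_ids[i], y_true=int(y[i]), y_pred=pred,
            selected_idx=[int(j) for j in sel],
            selected=[table.feature_ids[j] for j in sel]))
    metrics = compute_metrics([f.y_pred for f in results],
                              [f.y_true for f in results])
    return CvRun(folds=results, metrics=metrics, selector=selector,
                 classifier=classifier, seed=seed)


def permutation_test(table: FeatureTable, labels: CohortLabels,
                     selector: SelectorSpec = SelectorSpec(),
                     classifier: ClassifierSpec = ClassifierSpec(),
                     n_permutations: int = 1000, seed: int = 0,
                     cv_run: Optional[CvRun] = None,
                     refit_selection: bool = False) -> PermutationNull:
    """Permutation null for LOOCV accuracy.

    Labels are shuffled once per iteration and the cross-validation is
    re-run with each fold's feature set frozen to the true-label selection
    for that fold (only classifiers are refit).  ``refit_selection=True``
    instead re-runs the embedded selection on the shuffled labels (a
    stricter, non-default scheme).  Reports the z-score of the observed
    accuracy against the null and the +1-corrected empirical p-value.
    """
    X, y, folds = _fold_design(table, labels, selector,
                               classifier.standardize, seed)
    n = len(y)
    if cv_run is None:
        cv_run = run_nested_loocv(table, labels, selector, classifier, seed)
    observed = cv_run.metrics.accuracy
    frozen = {f_i: np.asarray(run_fold.selected_idx)
              for (f_i, *_), run_fold in zip(folds, cv_run.folds)}

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for p_i in range(n_permutations):
        y_perm = rng.permutation(y)
        correct = 0
        for i, tr, X_tr, X_te, sel in folds:
            if refit_selection:
                sel_p = _select(selector, X_tr if classifier.standardize
                                else X[tr], y_perm[tr], seed)
                # X_tr here is already column-subset; redo from full matrix
                if classifier.standardize:
                    scaler = StandardScaler().fit(X[tr])
                    Xt = scaler.transform(X[tr])[:, sel_p]
                    Xe = scaler.transform(X[i:i + 1])[:, sel_p]
                else:
                    Xt, Xe = X[np.ix_(tr, sel_p)], X[i:i + 1][:, sel_p]
            else:
                Xt, Xe = X_tr, X_te
            clf = _make_classifier(classifier, n)
            clf.fit(Xt, y_perm[tr])
            correct += int(clf.predict(Xe)[0] == y_perm[i])
        null[p_i] = correct / n

    sd = float(null.std())
    if sd == 0.0:
        warnings.warn("degenerate permutation null (sd = 0); z undefined")
        z = None
    else:
        z = float((observed - null.mean()) / sd)
    p_emp = float((1 + np.sum(null >= observed)) / (n_permutations + 1))
    return PermutationNull(null_accuracies=null, observed=observed, z=z,
                           p_empirical=p_emp, n_permutations=n_permutations)


def run_grid(table: FeatureTable, labels: CohortLabels,
             selectors: Sequence[SelectorSpec] = tuple(
                 SelectorSpec(method=m) for m in SELECTOR_METHODS),
             classifiers: Sequence[ClassifierSpec] = tuple(
                 ClassifierSpec(kind=c) for c in CLASSIFIER_KINDS),
             seed: int = 0) -> list[CvRun]:
    """All selector x classifier combinations under a shared seed policy."""
    return [run_nested_loocv(table, labels, sel, clf, seed=seed)
            for sel in selectors for clf in classifiers]


def grid_summary(runs: Sequence[CvRun]):
    """Five-metric summary table, one row per grid cell."""
    import pandas as pd
    rows = []
    for r in runs:
        rows.append({"selector": r.selector.method,
                     "classifier": r.classifier.kind,
                     **r.metrics.as_dict()})
    return pd.DataFrame(rows)
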