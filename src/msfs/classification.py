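"""Six-class tumor-size classification and cross-validated evaluation.

Classifiers: one-vs-rest linear SVM (C = 1), Gaussian naive Bayes, and a
probabilistic neural network (PNN) implemented from its definition — input,
pattern, summation and output layers, i.e. a Gaussian-kernel class-density
score with a single spread parameter (default 0.1), equal class weighting in
the summation layer (mean over patterns, so class imbalance does not bias
scores).

Evaluation follows the tumor-screening convention: the tumor-free class is
the negative class; TP counts tumor records assigned their exact size class,
FN tumor records assigned any wrong class, TN correctly identified tumor-free
records, FP tumor-free records called tumorous.  Accuracy = (TP+TN)/total
(equal to the confusion-matrix trace over total), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), all in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import LinearSVC

MODEL_SPECS = ("svm_linear", "gaussian_nb", "pnn")


@dataclass
class FoldPlan:
    """Stratified fold assignment: folds partition records, sizes differ <= 1."""

    k: int
    assignments: np.ndarray
    seed: int


@dataclass
class ConfusionMatrix:
    """counts[i, j] = records of true class i predicted as class j."""

    counts: np.ndarray
    class_order: np.ndarray  # ascending; index 0 is the negative (no-tumor) class


@dataclass
class EvalReport:
    """Per-fold and averaged accuracy / sensitivity / specificity (percent)."""

    model: str
    k: int
    fold_accuracy: List[float]
    fold_sensitivity: List[float]
    fold_specificity: List[float]
    confusions: List[ConfusionMatrix]
    accuracy: float = 0.0
    sensitivity: float = 0.0
    specificity: float = 0.0

    def __post_init__(self):
        self.accuracy = float(np.mean(self.fold_accuracy))
        self.sensitivity = float(np.nanmean(self.fold_sensitivity))
        self.specificity = float(np.nanmean(self.fold_specificity))


def make_folds(n: int, k: int, labels: np.ndarray, seed: int = 0) -> FoldPlan:
    """Seeded stratified k-fold plan over n records."""
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValueError("labels must have length n")
    if k > n:
        raise ValueError(f"k = {k} exceeds n = {n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    assignments = np.empty(n, dtype=int)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        # stratification impossible (a class has < k members): plain shuffled folds
        warnings.warn(
            "make_folds: smallest class has fewer members than k; "
            "falling back to unstratified folds",
            RuntimeWarning,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def pnn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    spread: float = 0.1,
) -> np.ndarray:
    """PNN prediction: argmax over classes of the mean Gaussian-kernel score.

    score_c(x) = mean_{i in class c} exp(-||x - x_i||^2 / (2 spread^2)),
    computed in log space for numerical stability; ties resolve to the lower
    class label.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    classes = np.unique(train_y)
    d2 = cdist(test_X, train_X, metric="sqeuclidean")
    log_kernel = -d2 / (2.0 * spread**2)
    log_scores = np.column_stack(
        [
            logsumexp(log_kernel[:, train_y == c], axis=1) - np.log((train_y == c).sum())
            for c in classes
        ]
    )
    return classes[np.argmax(log_scores, axis=1)]  # argmax keeps the first (lower) class on ties


def train_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    model_spec: str,
    spread: float = 0.1,
    random_state: int = 0,
) -> np.ndarray:
    """Fit one classifier on the training fold and predict the test fold."""
    train_y = np.asarray(train_y)
    if np.unique(train_y).size < 2:
        raise ValueError("training set contains a single class")
    if model_spec == "svm_linear":
        clf = LinearSVC(C=1.0, random_state=random_state)
        clf.fit(train_X, train_y)
        return clf.predict(test_X)
    if model_spec == "gaussian_nb":
        clf = GaussianNB()
        clf.fit(train_X, train_y)
        return clf.predict(test_X)
    if model_spec == "pnn":
        return pnn_predict(train_X, train_y, test_X, spread=spread)
    raise ValueError(f"unknown model_spec {model_spec!r}; use one of {MODEL_SPECS}")


def score(confusion: ConfusionMatrix) -> Tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent for one confusion table.

    The first class in ``class_order`` is the negative (tumor-free) class:
    TP = exact-size-correct tumor records, FN = any misassigned tumor record,
    TN = correctly identified tumor-free records, FP = tumor-free records
    assigned a size class.  Sensitivity/specificity are NaN (with a warning)
    when their denominator class is absent from the table.
    """
    c = np.asarray(confusion.counts, dtype=float)
    if c.size == 0 or c.sum() == 0:
        raise ValueError("empty confusion matrix")
    total = c.sum()
    tn = c[0, 0]
    fp = c[0, 1:].sum()
    tp = np.trace(c[1:, 1:])
    fn = c[1:].sum() - tp
    accuracy = 100.0 * (tp + tn) / total
    sensitivity = np.nan
    specificity = np.nan
    if tp + fn > 0:
        sensitivity = 100.0 * tp / (tp + fn)
    else:
        warnings.warn("score: no positive-class records in this table", RuntimeWarning)
    if tn + fp > 0:
        specificity = 100.0 * tn / (tn + fp)
    else:
        warnings.warn("score: no negative-class records in this table", RuntimeWarning)
    return float(accuracy), float(sensitivity), float(specificity)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    model_spec: str,
    k: int = 10,
    seed: int = 0,
    spread: float = 0.1,
    standardize: bool = True,
) -> EvalReport:
    """Stratified k-fold cross-validation of one classifier.

    Features are standardized with training-fold statistics before fitting
    (``standardize=True``), which keeps the PNN spread meaningful across
    datasets.  Emits one confusion matrix per fold plus averaged metrics.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and np.asarray(y).shape[0] != 1:
        X = X.T
    y = np.asarray(y)
    plan = make_folds(X.shape[0], k, y, seed=seed)
    classes = np.unique(y)
    accs, sens, specs, confs = [], [], [], []
    for fold in range(k):
        test = plan.assignments == fold
        train = ~test
        Xtr, Xte = X[train], X[test]
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        pred = train_predict(Xtr, y[train], Xte, model_spec, spread=spread, random_state=seed)
        counts = sk_confusion(y[test], pred, labels=classes)
        cm = ConfusionMatrix(counts=counts, class_order=classes)
        a, s, sp = score(cm)
        accs.append(a)
        sens.append(s)
        specs.append(sp)
        confs.append(cm)
    return EvalReport(
        model=model_spec,
        k=k,
        fold_accuracy=accs,
        fold_sensitivity=sens,
        fold_specificity=specs,
        confusions=confs,
    )
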