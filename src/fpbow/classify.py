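"""The five downstream classifiers and the binary evaluation formulas.

Classifiers: logistic regression, k-nearest neighbours (k = 3), random
forest, decision tree and an RBF support-vector machine.  Logistic
regression, random forest and decision tree are seeded with random_state 42
so repeated runs agree; KNN and SVM are deterministic given the data.

Metrics: accuracy, precision, recall and F1 over the TP/FP/FN/TN counts,
with F1 computed in its 2·TP / (2·TP + FP + FN) form.  A metric whose
denominator is zero is reported as NaN (an explicit undefined marker),
never silently as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClassifierSpec",
    "MetricsReport",
    "make_classifier",
    "fit_predict",
    "confusion",
    "metrics",
    "evaluate",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("lr", "knn", "rf", "dt", "svm")
SEEDED_RANDOM_STATE = 42


@dataclass(frozen=True)
class ClassifierSpec:
    """One classical classifier with its reference settings."""

    name: Literal["lr", "knn", "rf", "dt", "svm"]
    knn_neighbors: int = 3
    random_state: int = SEEDED_RANDOM_STATE
    svm_kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")


def make_classifier(spec: ClassifierSpec | str):
    if isinstance(spec, str):
        spec = ClassifierSpec(name=spec)
    if spec.name == "lr":
        return LogisticRegression(random_state=spec.random_state, max_iter=2000)
    if spec.name == "knn":
        return KNeighborsClassifier(n_neighbors=spec.knn_neighbors)
    if spec.name == "rf":
        return RandomForestClassifier(random_state=spec.random_state)
    if spec.name == "dt":
        return DecisionTreeClassifier(random_state=spec.random_state)
    return SVC(kernel=spec.svm_kernel)


def fit_predict(
    spec: ClassifierSpec | str,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
) -> np.ndarray:
    """Fit one classifier and label the test rows.

    Single-class training labels degrade to a constant classifier with a
    warning rather than an exception, so a sweep over many grid cells
    survives a degenerate cell.
    """
    train_labels = np.asarray(train_labels)
    if not np.isin(train_labels, (0, 1)).all():
        raise ValueError("training labels must be binary 0/1")
    if np.unique(train_labels).size < 2:
        only = int(train_labels[0])
        warnings.warn(f"single-class training labels; predicting constant {only}")
        return np.full(test_features.shape[0], only, dtype=int)
    if not (np.isfinite(train_features).all() and np.isfinite(test_features).all()):
        raise ValueError("features must be finite")
    clf = make_classifier(spec)
    clf.fit(train_features, train_labels)
    return clf.predict(test_features).astype(int)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) counts; the four partition the N pairs."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return tp, fp, fn, tn


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def metrics(tp: int, fp: int, fn: int, tn: int) -> MetricsReport:
    """Accuracy, precision, recall, F1 from confusion counts.

    accuracy  = (TP + TN) / N
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2·TP / (2·TP + FP + FN)

    A zero denominator yields NaN for that metric; note F1's form stays
    defined even when precision is undefined, as long as 2·TP + FP + FN > 0.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("all confusion counts are zero")
    precision = tp / (tp + fp) if (tp + fp) else math.nan
    recall = tp / (tp + fn) if (tp + fn) else math.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else math.nan
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / n, precision=precision, recall=recall, f1=f1,
    )


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    return metrics(*confusion(y_true, y_pred))
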