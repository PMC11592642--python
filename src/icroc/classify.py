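"""Confusion-matrix metrics and criterion scoring of binary classifiers.

Classifiers are evaluated with stratified k-fold cross-validation: every
instance is scored exactly once by a model not trained on it.  The
out-of-fold scores yield the empirical ROC, its trapezoidal AUC, and —
through the correlation of the curve's (FPR, TPR) points — the AIC-ROC and
ICOMP-ROC criteria with n equal to the number of instances.  Hard
predictions threshold the scores at 0.5 and feed the usual confusion
metrics (accuracy, precision, recall, F1, error rate); metrics with a zero
denominator are reported as flagged NaN, never coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .criteria import CriterionConfig, DEFAULT_CONFIG, c1_complexity, correlation_from_curve, \
    aic_roc, icomp_roc, ifim_bivariate_corr
from .roc import auc as _auc, empirical_roc

__all__ = [
    "FeatureTable",
    "ConfusionCounts",
    "MetricsReport",
    "make_classifier",
    "CLASSIFIER_NAMES",
    "confusion_counts",
    "metrics_from_confusion",
    "cross_validated_scores",
    "evaluate_classifier",
    "evaluate_portfolio",
]

CLASSIFIER_NAMES = ("LR", "SVM", "NB", "KNN", "DT")


def make_classifier(name: str, seed: int = 0):
    """A fresh estimator for one of the five classifier families.

    Library defaults throughout, except: logistic regression gets a larger
    iteration cap so the solver always converges on standardized features,
    and the SVM is fitted with Platt probability scaling so every model
    exposes a [0, 1] score.
    """
    if name == "LR":
        return LogisticRegression(max_iter=2000)
    if name == "SVM":
        return SVC(probability=True, random_state=seed)
    if name == "NB":
        return GaussianNB()
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


@dataclass
class FeatureTable:
    """Numeric instance-by-feature matrix with a binary label vector."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y).astype(int).ravel()
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be 2-D with one row per label")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing or non-finite values")
        if set(np.unique(self.y)) != {0, 1}:
            raise ValueError("labels must contain both classes 0 and 1")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match the number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, mask) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.d or not mask.any():
            raise ValueError("mask must match the feature count and keep >= 1 feature")
        names = [nm for nm, keep in zip(self.feature_names, mask) if keep]
        return FeatureTable(X=self.X[:, mask], y=self.y, feature_names=names)

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label_column] = self.y
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_column: str = "label") -> "FeatureTable":
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        y = df[label_column].to_numpy()
        X = df.drop(columns=[label_column])
        return cls(X=X.to_numpy(dtype=float), y=y, feature_names=list(X.columns))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Cross-tabulate 0/1 predictions against 0/1 truth (class 1 positive)."""
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics_from_confusion(c: ConfusionCounts) -> dict:
    """Accuracy, precision, recall, F1 and error rate from raw counts.

    Undefined ratios (no predicted positives, no actual positives, or both
    precision and recall zero for F1) come back as NaN with the metric name
    listed under ``"undefined"``.
    """
    if c.n <= 0:
        raise ValueError("confusion counts are empty")
    undefined: list[str] = []
    accuracy = (c.tp + c.tn) / c.n
    error_rate = (c.fp + c.fn) / c.n
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision, undefined = math.nan, undefined + ["precision"]
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall, undefined = math.nan, undefined + ["recall"]
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
        undefined.append("f1")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "error_rate": error_rate,
        "undefined": tuple(undefined),
    }


def cross_validated_scores(
    table: FeatureTable, clf, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold positive-class scores and 0.5-thresholded predictions.

    ``clf`` is a classifier name from :data:`CLASSIFIER_NAMES` or any
    sklearn-style estimator exposing ``predict_proba``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n_minority = int(np.bincount(table.y).min())
    if n_minority < k:
        raise ValueError(
            f"minority class has {n_minority} instances < k={k}; use a smaller k"
        )
    estimator = make_classifier(clf, seed) if isinstance(clf, str) else clf
    scores = np.empty(table.n, dtype=float)
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in folds.split(table.X, table.y):
        model = clone(estimator)
        model.fit(table.X[train_idx], table.y[train_idx])
        proba = model.predict_proba(table.X[test_idx])
        pos_col = list(model.classes_).index(1)
        scores[test_idx] = proba[:, pos_col]
    return scores, (scores >= 0.5).astype(int)


@dataclass
class MetricsReport:
    """Confusion metrics plus AUC and both criteria for one classifier run."""

    classifier: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    error_rate: float
    auc: float
    aic_roc: float
    icomp_roc: float
    c1: float
    r: float
    n: int
    undefined: tuple = ()
    feature_subset: np.ndarray | None = None

    def to_row(self) -> dict:
        return {
            "classifier": self.classifier,
            "Accuracy": self.accuracy,
            "Precision": self.precision,
            "Recall": self.recall,
            "F1Score": self.f1,
            "Error Rate": self.error_rate,
            "AUC": self.auc,
            "AIC-ROC": self.aic_roc,
            "ICOMP-ROC": self.icomp_roc,
        }


def evaluate_classifier(
    table: FeatureTable,
    clf="LR",
    k: int = 5,
    seed: int = 0,
    config: CriterionConfig = DEFAULT_CONFIG,
) -> MetricsReport:
    """Score one classifier on one feature table via out-of-fold predictions."""
    name = clf if isinstance(clf, str) else type(clf).__name__
    scores, preds = cross_validated_scores(table, clf, k=k, seed=seed)
    curve = empirical_roc(scores, table.y)
    summary = correlation_from_curve(curve, n=table.n)
    c1 = c1_complexity(ifim_bivariate_corr(summary.r, summary.n))
    metrics = metrics_from_confusion(confusion_counts(table.y, preds))
    return MetricsReport(
        classifier=name,
        accuracy=metrics["accuracy"],
        precision=metrics["precision"],
        recall=metrics["recall"],
        f1=metrics["f1"],
        error_rate=metrics["error_rate"],
        auc=_auc(curve),
        aic_roc=aic_roc(summary, config),
        icomp_roc=icomp_roc(summary, config),
        c1=c1,
        r=summary.r,
        n=table.n,
        undefined=metrics["undefined"],
    )


def evaluate_portfolio(
    table: FeatureTable, k: int = 5, seed: int = 0, config: CriterionConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """One report row per classifier family, in the conventional table layout."""
    rows = [
        evaluate_classifier(table, name, k=k, seed=seed, config=config).to_row()
        for name in CLASSIFIER_NAMES
    ]
    return pd.DataFrame(rows).set_index("classifier")
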