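"""Confusion matrices, per-class precision/sensitivity, stratified k-fold CV.

Internals keep fractions in [0, 1]; percent formatting belongs to the
reporting layer.  A class never predicted has *undefined* precision,
reported as NaN (never 0) and excluded from macro averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold

from .classification import autoscale, fit_oplsda, predict_oplsda
from .phenotyping import FEATURE_COLUMNS

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion_matrix",
    "class_metrics",
    "cross_validate",
    "resubstitution_metrics",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    classes: list[str]
    counts: np.ndarray  # K x K, rows = true, cols = predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        K = len(self.classes)
        if self.counts.shape != (K, K) or np.any(self.counts < 0):
            raise ValueError("counts must be a nonnegative K x K matrix")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class ClassMetrics:
    classes: list[str]
    precision: np.ndarray    # NaN where the class was never predicted
    sensitivity: np.ndarray  # NaN where the class has no true samples
    total_accuracy: float

    def as_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "precision": [None if np.isnan(v) else float(v) for v in self.precision],
            "sensitivity": [None if np.isnan(v) else float(v) for v in self.sensitivity],
            "total_accuracy": float(self.total_accuracy),
        }


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    classes: Sequence[str],
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    unknown = (set(true_labels) | set(predicted_labels)) - set(classes)
    if unknown:
        raise ValueError(f"labels not in the class list: {sorted(unknown)}")
    counts = skmetrics.confusion_matrix(true_labels, predicted_labels, labels=list(classes))
    return ConfusionMatrix(list(classes), counts)


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, np.nan)
        sensitivity = np.where(row > 0, diag / row, np.nan)
    if np.any(col == 0):
        never = [c for c, n in zip(cm.classes, col) if n == 0]
        logger.info("precision undefined (never predicted) for: %s", never)
    return ClassMetrics(list(cm.classes), precision, sensitivity, float(diag.sum() / total))


def _features_and_labels(features, labels):
    if isinstance(features, pd.DataFrame):
        X = features[FEATURE_COLUMNS].to_numpy(float)
        if labels is None:
            labels = features["class"].tolist()
    else:
        X = np.asarray(features, dtype=float)
    if labels is None:
        raise ValueError("labels are required when features is a bare matrix")
    return X, list(labels)


def cross_validate(
    features,
    labels: Sequence[str] | None = None,
    k: int = 7,
    A: int | None = None,
    A_ortho: int | None = None,
    seed: int = 0,
) -> tuple[ConfusionMatrix, ClassMetrics]:
    """Stratified k-fold CV of the OPLS-DA classifier; pooled predictions.

    ``features`` is either a feature table (DataFrame with the five feature
    columns and, if ``labels`` is None, a ``class`` column) or a raw n×p
    matrix.  Scaling and model fitting happen inside each training fold
    only.  If the smallest class has fewer than ``k`` members, k is reduced
    to that count (logged).  Deterministic for a fixed seed.
    """
    X, y = _features_and_labels(features, labels)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    min_count = min(y.count(c) for c in classes)
    k_eff = min(k, min_count)
    if k_eff < k:
        logger.warning("reducing k from %d to %d (smallest class size)", k, k_eff)
    if k_eff < 2:
        raise ValueError("smallest class has fewer than 2 samples; cannot cross-validate")
    y_arr = np.asarray(y)
    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y_arr):
        scaled = autoscale(X[train])
        model = fit_oplsda(scaled, list(y_arr[train]), A=A, A_ortho=A_ortho)
        pred = predict_oplsda(model, X[test])
        pooled_true.extend(y_arr[test])
        pooled_pred.extend(pred.predicted_label)
    cm = confusion_matrix(pooled_true, pooled_pred, classes)
    return cm, class_metrics(cm)


def resubstitution_metrics(
    features,
    labels: Sequence[str] | None = None,
    A: int | None = None,
    A_ortho: int | None = None,
) -> tuple[ConfusionMatrix, ClassMetrics]:
    """Training-set (resubstitution) metrics of a single fitted model."""
    X, y = _features_and_labels(features, labels)
    model = fit_oplsda(autoscale(X), y, A=A, A_ortho=A_ortho)
    pred = predict_oplsda(model, X)
    cm = confusion_matrix(y, pred.predicted_label, model.class_labels)
    return cm, class_metrics(cm)
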