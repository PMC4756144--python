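"""Cross-validated performance measurement.

Binary classification quality is summarized from the confusion matrix
(TP, TN, FP, FN) as

    SN  = TP / (TP + FN)                       (sensitivity / recall)
    SP  = TN / (TN + FP)                       (specificity)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) /
          sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP))   (Matthews correlation)

MCC is the key measurement here: it stays balanced under the 1:2
positive:negative class ratio where ACC does not.  A zero MCC
denominator is reported as 0 with an ``mcc_undefined`` flag.

Cross-validation is stratified tenfold by default: every sample is
predicted exactly once by a model trained on the other folds, and a
single pooled confusion matrix over all folds yields the report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .models import Classifier

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "make_folds",
    "compute_metrics",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @classmethod
    def from_labels(
        cls, y_true: np.ndarray, y_pred: np.ndarray, positive=1
    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have equal length")
        t = y_true == positive
        p = y_pred == positive
        return cls(
            tp=int(np.sum(t & p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    mcc_undefined: bool = False


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Evaluate SN, SP, ACC and MCC from a confusion matrix."""
    if cm.tp + cm.fn < 1 or cm.tn + cm.fp < 1:
        raise ValueError("need at least one true positive-class and one "
                         "true negative-class sample")
    sn = cm.tp / (cm.tp + cm.fn)
    sp = cm.tn / (cm.tn + cm.fp)
    acc = (cm.tp + cm.tn) / cm.total
    denom = math.sqrt(
        float(cm.tn + cm.fn) * (cm.tn + cm.fp) * (cm.tp + cm.fn) * (cm.tp + cm.fp)
    )
    if denom == 0:
        return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=0.0, mcc_undefined=True)
    mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / denom
    return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=mcc)


def make_folds(y: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Seeded stratified k-fold assignment (fold index per sample).

    Folds partition the samples; sizes differ by at most 1 and per-class
    counts per fold differ by at most 1.  If k exceeds the smallest class
    count, stratification is impossible and a plain shuffled k-fold split
    is used instead (with a warning).
    """
    y = np.asarray(y)
    n = y.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    _, class_counts = np.unique(y, return_counts=True)
    if k <= class_counts.min():
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        warnings.warn(
            f"k={k} exceeds the smallest class count {class_counts.min()}; "
            "falling back to unstratified folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), y)):
        folds[test_idx] = fold
    return folds


def cross_validate(
    engine_factory: Callable[[], Classifier],
    X: np.ndarray,
    y: np.ndarray,
    feature_indices: Sequence[int] | np.ndarray,
    folds: np.ndarray,
) -> tuple[MetricsReport, np.ndarray]:
    """Pooled cross-validation of an engine on a feature subset.

    Returns the metrics of the single pooled confusion matrix and the
    per-sample predicted labels (each sample predicted exactly once, by
    the model trained without its fold).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    feature_indices = np.asarray(feature_indices, dtype=int)
    if feature_indices.size == 0:
        raise ValueError("feature subset must be non-empty")
    folds = np.asarray(folds)
    if folds.shape[0] != X.shape[0]:
        raise ValueError("fold assignment length must match sample count")
    Xs = X[:, feature_indices]
    y_pred = np.empty_like(y)
    for fold in np.unique(folds):
        test = folds == fold
        train = ~test
        engine = engine_factory()
        try:
            engine.fit(Xs[train], y[train])
            y_pred[test] = engine.predict(Xs[test])
        except Exception as exc:  # annotate failures with the fold id
            raise RuntimeError(f"engine failed on fold {fold}: {exc}") from exc
    cm = ConfusionMatrix.from_labels(y, y_pred)
    return compute_metrics(cm), y_pred
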