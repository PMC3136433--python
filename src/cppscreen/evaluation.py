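"""Cross-validation, confusion-matrix statistics and baselines.

Metrics follow the conventional weighted panel: accuracy, class-weighted
true-positive rate (identical to accuracy/100 by construction),
class-weighted false-positive rate, and class-weighted ROC area computed
from decision values. Folds are stratified: with 34 negatives among 145
rows an unstratified 10-fold split can produce folds with no negatives at
all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datasets import LabeledDataset
from .errors import (DimensionError, EmptyInput, EmptySubset,
                     StratificationError)
from .svm import KernelParams, PukSvm, PukSvmResults, SVMConfig


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with CPP as the positive class."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("negative count")
        if self.total == 0:
            raise EmptyInput("all-zero confusion matrix")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass
class EvaluationReport:
    """The reporting panel: confusion matrix, accuracy (%), weighted
    TPR/FPR, class-weighted ROC area, per-class accuracies."""

    confusion: ConfusionMatrix
    accuracy: float
    tpr: float
    fpr: float
    roc_area: float | None = None
    cpp_accuracy: float = float("nan")
    noncpp_accuracy: float = float("nan")
    fold_seed: int | None = None
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        cm = self.confusion
        roc = f"{self.roc_area:.3f}" if self.roc_area is not None else "n/a"
        return "\n".join([
            "Classifier evaluation",
            "=" * 40,
            f"{'Total examples:':<26}{cm.total}",
            f"{'Confusion (tn fp fn tp):':<26}{cm.tn} {cm.fp} {cm.fn} {cm.tp}",
            f"{'Accuracy:':<26}{self.accuracy:.2f}%",
            f"{'True positive rate:':<26}{self.tpr:.3f}",
            f"{'False positive rate:':<26}{self.fpr:.3f}",
            f"{'ROC area:':<26}{roc}",
            f"{'CPP accuracy:':<26}{self.cpp_accuracy:.2f}%",
            f"{'Non-CPP accuracy:':<26}{self.noncpp_accuracy:.2f}%",
            "=" * 40,
        ])


def confusion_stats(cm: ConfusionMatrix) -> EvaluationReport:
    """Accuracy and the weighted rate panel from raw counts.

    Weighted TPR is per-class recall weighted by class support; weighted
    FPR weights, for each class, the fraction of the *other* class
    predicted as it.
    """
    n_pos = cm.tp + cm.fn
    n_neg = cm.tn + cm.fp
    total = cm.total
    recall_pos = cm.tp / n_pos if n_pos else 0.0
    recall_neg = cm.tn / n_neg if n_neg else 0.0
    fpr_pos = cm.fp / n_neg if n_neg else 0.0   # negatives called CPP
    fpr_neg = cm.fn / n_pos if n_pos else 0.0   # positives called non-CPP
    tpr = (n_pos * recall_pos + n_neg * recall_neg) / total
    fpr = (n_pos * fpr_pos + n_neg * fpr_neg) / total
    return EvaluationReport(
        confusion=cm,
        accuracy=100.0 * (cm.tp + cm.tn) / total,
        tpr=tpr, fpr=fpr,
        cpp_accuracy=100.0 * recall_pos,
        noncpp_accuracy=100.0 * recall_neg,
    )


def majority_baseline(n_pos: int, n_neg: int) -> float:
    """Accuracy (%) of always predicting the most frequent class."""
    if n_pos + n_neg <= 0:
        raise EmptyInput("empty dataset")
    return 100.0 * max(n_pos, n_neg) / (n_pos + n_neg)


def weighted_roc_area(y: np.ndarray, scores: np.ndarray) -> float:
    """Class-weighted average of per-class one-vs-rest ROC areas.

    For two classes the per-class areas coincide, so this equals the
    ordinary AUC of the CPP decision values; kept explicit to mirror the
    weighted reporting convention.
    """
    y = np.asarray(y)
    auc_pos = roc_auc_score((y == 1).astype(int), scores)
    auc_neg = roc_auc_score((y == -1).astype(int), -scores)
    w_pos = (y == 1).mean()
    return float(w_pos * auc_pos + (1 - w_pos) * auc_neg)


def _report_from_predictions(y: np.ndarray, yhat: np.ndarray,
                             scores: np.ndarray) -> EvaluationReport:
    cm = ConfusionMatrix(
        tn=int(((y == -1) & (yhat == -1)).sum()),
        fp=int(((y == -1) & (yhat == 1)).sum()),
        fn=int(((y == 1) & (yhat == -1)).sum()),
        tp=int(((y == 1) & (yhat == 1)).sum()),
    )
    report = confusion_stats(cm)
    if len(np.unique(y)) == 2:
        report.roc_area = weighted_roc_area(y, scores)
    return report


def cross_validate(dataset: LabeledDataset, k: int = 10, seed: int = 0,
                   subset: Sequence[str] | None = None,
                   config: SVMConfig = SVMConfig(),
                   kernel: KernelParams = KernelParams()) -> EvaluationReport:
    """Stratified k-fold CV; out-of-fold predictions pooled into one panel.

    Each fold refits normalization and the SVM on its training split only.
    """
    y = dataset.y
    n_min = min((y == 1).sum(), (y == -1).sum())
    if k < 2:
        raise StratificationError("k must be >= 2")
    if k > n_min:
        raise StratificationError(
            f"k={k} exceeds minority class size {n_min}")
    X = dataset.X if subset is None else _restrict(dataset, subset)
    Xv = X.to_numpy()
    yhat = np.zeros(len(y), dtype=int)
    scores = np.zeros(len(y), dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    for train_idx, test_idx in skf.split(Xv, y):
        res = PukSvm(Xv[train_idx], y[train_idx],
                     feature_names=list(X.columns),
                     kernel=kernel, config=config).fit()
        yhat[test_idx], scores[test_idx] = res.predict(Xv[test_idx])
    report = _report_from_predictions(y, yhat, scores)
    report.fold_seed = seed
    report.extra["k"] = k
    return report


def evaluate_on(results: PukSvmResults, dataset: LabeledDataset) -> EvaluationReport:
    """Single-pass evaluation of a fitted model on a dataset (no refit)."""
    missing = [f for f in results.feature_names if f not in dataset.X.columns]
    if missing:
        raise DimensionError(f"dataset lacks features {missing}")
    yhat, scores = results.predict(dataset.X[results.feature_names])
    return _report_from_predictions(dataset.y, yhat, scores)


def _restrict(dataset: LabeledDataset, subset: Sequence[str]):
    subset = list(subset)
    if not subset:
        raise EmptySubset("feature subset is empty")
    unknown = [s for s in subset if s not in dataset.X.columns]
    if unknown:
        raise EmptySubset(f"unknown feature names {unknown}")
    return dataset.X[subset]
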