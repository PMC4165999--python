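"""Confusion-based metrics, ROC/AUC, and stratified cross-validation.

The positive class (label 1) is the DNA-binding class.  Accuracy alone is a
poor yardstick on imbalanced data — a classifier calling everything negative
on a 1:9 set scores 90% accuracy with zero positive recall — so per-class
F-measure and AUC are first-class citizens here, alongside the
support-weighted averages.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "EvaluationReport",
    "confusion",
    "metrics",
    "roc_auc",
    "cross_validate",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionCounts":
        """The same counts with the roles of the classes exchanged."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp)


@dataclasses.dataclass(frozen=True)
class ClassMetrics:
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    undefined: tuple[str, ...] = ()  # which ratios were 0/0 and reported as 0


@dataclasses.dataclass(frozen=True)
class EvaluationReport:
    counts: ConfusionCounts
    positive: ClassMetrics
    negative: ClassMetrics
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f_measure: float
    auc: float | None
    folds: tuple[dict, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "counts": dataclasses.asdict(self.counts),
            "positive": dataclasses.asdict(self.positive),
            "negative": dataclasses.asdict(self.negative),
            "accuracy": self.accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f_measure": self.weighted_f_measure,
            "auc": self.auc,
            "folds": list(self.folds),
        }
        for key in ("positive", "negative"):
            d[key]["undefined"] = list(d[key]["undefined"])
        return d


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return y.astype(int)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Standard confusion counts with label 1 as the positive class."""
    yt = _check_binary(y_true)
    yp = _check_binary(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def metrics(c: ConfusionCounts) -> ClassMetrics:
    """Accuracy, precision, recall and F-measure from confusion counts.

    0/0 ratios are reported as 0 and flagged in ``undefined``.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    undefined = []
    accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        precision = 0.0
        undefined.append("precision")
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        recall = 0.0
        undefined.append("recall")
    else:
        recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        f = 0.0
        undefined.append("f_measure")
    else:
        f = 2 * precision * recall / (precision + recall)
    return ClassMetrics(accuracy, precision, recall, f, tuple(undefined))


def roc_auc(
    y_true: Sequence[int], scores: Sequence[float]
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus ROC curve points.

    AUC is the Mann-Whitney probability that a random positive outscores a
    random negative, ties counting one half — identical to the trapezoidal
    area under the ROC curve.  Returns (auc, fpr, tpr) with the curve
    anchored at (0,0) and (1,1).
    """
    yt = _check_binary(y_true)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise ValueError("y_true and scores must have equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int(yt.sum())
    n_neg = len(yt) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)  # average ranks give the half-tie credit
    auc = (ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(yt, s)
    return float(auc), fpr, tpr


TrainerFn = Callable[[pd.DataFrame, np.ndarray], Callable[[pd.DataFrame], tuple[np.ndarray, np.ndarray]]]


def cross_validate(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    trainer: TrainerFn,
    folds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with pooled (micro) confusion.

    ``trainer(X_train, y_train)`` must return a predictor ``X -> (labels,
    scores)``.  Fold assignment is deterministic given the seed.  The report
    carries the pooled confusion/AUC plus a per-fold breakdown.
    """
    y = _check_binary(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} samples; needs >= {folds}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled_pred = np.empty_like(y)
    pooled_scores = np.empty(len(y), dtype=float)
    fold_records = []
    for fold_i, (tr, te) in enumerate(skf.split(matrix, y)):
        predictor = trainer(matrix.iloc[tr], y[tr])
        pred, scores = predictor(matrix.iloc[te])
        pooled_pred[te] = pred
        pooled_scores[te] = scores
        fc = confusion(y[te], pred)
        fm = metrics(fc)
        fold_records.append(
            {
                "fold": fold_i,
                "counts": dataclasses.asdict(fc),
                "accuracy": fm.accuracy,
                "positive_f_measure": fm.f_measure,
            }
        )
    return evaluate(y, pooled_pred, pooled_scores, folds=tuple(fold_records))


def evaluate(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Sequence[float] | None = None,
    folds: tuple[dict, ...] = (),
) -> EvaluationReport:
    """Assemble a full report from predictions (and optional scores for AUC)."""
    c = confusion(y_true, y_pred)
    pos = metrics(c)
    neg = metrics(c.swapped())
    n_pos = c.tp + c.fn
    n_neg = c.tn + c.fp
    total = c.total
    auc = None
    if scores is not None:
        auc, _, _ = roc_auc(y_true, scores)
    return EvaluationReport(
        counts=c,
        positive=pos,
        negative=neg,
        accuracy=pos.accuracy,
        weighted_precision=(n_pos * pos.precision + n_neg * neg.precision) / total,
        weighted_recall=(n_pos * pos.recall + n_neg * neg.recall) / total,
        weighted_f_measure=(n_pos * pos.f_measure + n_neg * neg.f_measure) / total,
        auc=auc,
        folds=folds,
    )
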