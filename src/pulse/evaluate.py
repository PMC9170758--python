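"""Classification metrics: ROC/AUC, precision, recall, F1, and MCC.

AUC is the Mann–Whitney pair statistic (fraction of positive/negative
pairs ranked correctly, ties counted one half), equivalently the
trapezoidal area under the ROC curve.  The confusion-based metrics use a
strict score > threshold rule (default threshold 0.5, matching the
Ψ-call indicator used by the transcript score).  Metrics with a zero
denominator are reported as 0 with an explicit ``degenerate`` flag
rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .model import CVResult, TrainedModel
from .seqdata import LabeledSample, encode_samples


@dataclass
class EvalMetrics:
    auc: float
    precision: float
    recall: float
    f1: float
    mcc: float
    threshold: float
    counts: dict[str, int]
    degenerate: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
            "threshold": self.threshold,
            **self.counts,
            "degenerate": self.degenerate,
        }


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    return scores, labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; ties get half credit."""
    scores, labels = _check(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def roc_points(scores, labels) -> np.ndarray:
    """(FPR, TPR) table of the ROC curve, for export."""
    scores, labels = _check(scores, labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])


def confusion_metrics(scores, labels, threshold: float = 0.5) -> EvalMetrics:
    """Precision/recall/F1/MCC from the strict ``score > threshold`` call."""
    scores, labels = _check(scores, labels)
    pred = scores > threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))

    degenerate: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ratio(tp * tn - fp * fn, mcc_den, "mcc")

    try:
        auc = roc_auc(scores, labels)
    except ValueError:
        auc = 0.0
        degenerate.append("auc")
    return EvalMetrics(
        auc=auc, precision=precision, recall=recall, f1=f1, mcc=mcc,
        threshold=threshold, counts={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        degenerate=degenerate,
    )


def evaluate_cv(cv: CVResult, threshold: float = 0.5) -> EvalMetrics:
    """Metrics on the pooled out-of-fold predictions (not fold averages)."""
    if np.isnan(cv.scores).any():
        raise ValueError("pooled out-of-fold predictions are incomplete")
    return confusion_metrics(cv.scores, cv.labels, threshold)


def cross_apply(
    model: TrainedModel,
    foreign_samples: Sequence[LabeledSample],
    threshold: float = 0.5,
) -> EvalMetrics:
    """Apply a trained model to another labeled set without retraining,
    e.g. the cross-species protocol (train on one species, test on the
    other) or an imbalanced held-out set."""
    X, y = encode_samples(foreign_samples)
    return confusion_metrics(model.predict(X), y, threshold)
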