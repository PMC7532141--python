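"""Confusion-count metrics, f1 and the three AUROC aggregations.

Acc = (tp+tn)/(tp+fp+fn+tn), Rec = tp/(tp+fn), Prec = tp/(tp+fp),
f1 = 2*Prec*Rec/(Prec+Rec); multiclass metrics are one-vs-rest per class.
AUROC is computed from the rank statistic (Mann-Whitney with tie-averaged
ranks); micro pools all (sample, label) pairs, macro averages per-label
scores unweighted, weighted averages by label prevalence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "confusion_metrics", "auroc"]


@dataclass
class EvalReport:
    """Confusion counts plus the derived metric set for one prediction run."""

    confusion: np.ndarray                 # [K, K], rows=true, cols=predicted
    accuracy: float
    precision: np.ndarray                 # per class, one-vs-rest
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    zero_division_classes: list[int] = field(default_factory=list)
    auroc_micro: float | None = None
    auroc_macro: float | None = None
    auroc_weighted: float | None = None

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_f1": self.macro_f1,
            "zero_division_classes": self.zero_division_classes,
        }
        for k in ("auroc_micro", "auroc_macro", "auroc_weighted"):
            if getattr(self, k) is not None:
                d[k] = getattr(self, k)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def confusion_metrics(
    true_labels: Sequence[int], predicted_labels: Sequence[int], num_classes: int
) -> EvalReport:
    """Confusion matrix and Acc/Rec/Prec/f1 from hard label predictions.

    Zero-denominator metrics are reported as 0 and the class is flagged in
    ``zero_division_classes``.
    """
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty evaluation input")
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("true and predicted labels must be equal-length 1-D arrays")
    k = int(num_classes)
    if y.min() < 0 or y.max() >= k or p.min() < 0 or p.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (y, p), 1)

    total = confusion.sum()
    accuracy = float(np.trace(confusion) / total)
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    flagged: list[int] = []
    precision = np.zeros(k)
    recall = np.zeros(k)
    f1 = np.zeros(k)
    for c in range(k):
        flag = False
        if tp[c] + fp[c] > 0:
            precision[c] = tp[c] / (tp[c] + fp[c])
        else:
            flag = True
        if tp[c] + fn[c] > 0:
            recall[c] = tp[c] / (tp[c] + fn[c])
        else:
            flag = True
        if precision[c] + recall[c] > 0:
            f1[c] = 2.0 * precision[c] * recall[c] / (precision[c] + recall[c])
        else:
            flag = True
        if flag:
            flagged.append(c)
    return EvalReport(
        confusion=confusion,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_f1=float(f1.mean()),
        zero_division_classes=flagged,
    )


def _auroc_binary(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUROC with tie-averaged ranks (Mann-Whitney)."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auroc(scores: np.ndarray, labels: np.ndarray, mode: str = "macro") -> float:
    """Area under the ROC curve for ``[N]`` or ``[N, L]`` score arrays.

    ``micro`` pools every (sample, label) pair into one ranking; ``macro``
    is the unweighted mean of per-label AUROCs; ``weighted`` weights each
    label by its positive count.  Label columns without both a positive and
    a negative are excluded from macro/weighted with a logged warning; a
    fully degenerate pooled ranking is an error.
    """
    if mode not in ("micro", "macro", "weighted"):
        raise ValueError(f"mode must be micro|macro|weighted, got {mode!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must share a shape")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if scores.ndim == 1:
        scores = scores[:, None]
        labels = labels[:, None]
    if mode == "micro":
        return _auroc_binary(scores.ravel(), labels.ravel())
    per_label: list[float] = []
    weights: list[float] = []
    for col in range(scores.shape[1]):
        y = labels[:, col]
        if y.sum() == 0 or y.sum() == y.size:
            logger.warning("excluding degenerate label column %d from %s AUROC", col, mode)
            continue
        per_label.append(_auroc_binary(scores[:, col], y))
        weights.append(float(y.sum()))
    if not per_label:
        raise ValueError("all label columns are degenerate (all-positive or all-negative)")
    if mode == "macro":
        return float(np.mean(per_label))
    return float(np.average(per_label, weights=weights))
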