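"""Locomotion-score classification metrics.

Per-class metrics are obtained by one-vs-rest reduction of the multiclass
confusion matrix: for class *i*, TP is the diagonal entry, FN the rest of
row *i*, FP the rest of column *i*, and TN everything else.  From these,

    accuracy_i   = (TP + TN) / (TP + TN + FP + FN) * 100%
    specificity  = TN / (TN + FP)
    sensitivity  = recall = TP / (TP + FN)
    precision    = TP / (TP + FP)
    F1_i         = 2 * precision * recall / (precision + recall)
    Macro-F1     = mean over classes of F1_i

Macro-averaging gives every class equal weight, which matters for the
imbalanced locomotion-score cohorts this package targets (sound cows
typically outnumber severely lame ones several-fold).

Because the binary accuracy formula does not extend uniquely to three
classes, :func:`class_metrics` reports both the overall multiclass accuracy
(trace / total, the primary number) and the macro-average of the per-class
one-vs-rest accuracies.  All ratios with a zero denominator are reported
as 0 by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Locomotion scores: 1 = sound, 2 = mildly lame, 3 = severely lame.
DEFAULT_LABELS: tuple[int, ...] = (1, 2, 3)


def _safe_div(num: float, den: float, what: str = "") -> float:
    if den == 0:
        if what:
            logger.debug("zero denominator for %s; reporting 0 by convention", what)
        return 0.0
    return num / den


def confusion_matrix(y_true, y_pred, labels: tuple = DEFAULT_LABELS) -> np.ndarray:
    """Confusion matrix with rows = true label, columns = predicted label.

    Raises ``ValueError`` on length mismatch or labels outside ``labels``.
    """
    y_true = np.asarray(list(y_true))
    y_pred = np.asarray(list(y_pred))
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"true/predicted length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    index = {lab: i for i, lab in enumerate(labels)}
    m = len(labels)
    cm = np.zeros((m, m), dtype=int)
    for t, p in zip(y_true.tolist(), y_pred.tolist()):
        if t not in index or p not in index:
            raise ValueError(f"label outside {labels}: true={t!r}, pred={p!r}")
        cm[index[t], index[p]] += 1
    return cm


def one_vs_rest_counts(cm: np.ndarray, label, labels: tuple = DEFAULT_LABELS):
    """``(TP, TN, FP, FN)`` for ``label`` against all other classes."""
    cm = np.asarray(cm)
    if cm.shape != (len(labels), len(labels)):
        raise ValueError(f"confusion matrix shape {cm.shape} does not match {labels}")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    i = labels.index(label)
    tp = int(cm[i, i])
    fn = int(cm[i, :].sum() - tp)
    fp = int(cm[:, i].sum() - tp)
    tn = int(cm.sum() - tp - fn - fp)
    return tp, tn, fp, fn


@dataclass
class ClassMetrics:
    """Per-class one-vs-rest metrics plus overall summaries for one matrix."""

    labels: tuple
    cm: np.ndarray
    per_class: dict = field(default_factory=dict)
    accuracy_pct: float = 0.0          # trace / total * 100 (primary)
    macro_ovr_accuracy_pct: float = 0.0  # mean of per-class one-vs-rest accuracies
    macro_f1: float = 0.0

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion_matrix": np.asarray(self.cm).tolist(),
            "per_class": {str(k): dict(v) for k, v in self.per_class.items()},
            "overall": {
                "accuracy_pct": self.accuracy_pct,
                "macro_ovr_accuracy_pct": self.macro_ovr_accuracy_pct,
                "macro_f1": self.macro_f1,
            },
        }


def class_metrics(cm: np.ndarray, labels: tuple = DEFAULT_LABELS) -> ClassMetrics:
    """Evaluate sensitivity/specificity/precision/F1 per class and Macro-F1."""
    cm = np.asarray(cm)
    total = int(cm.sum())
    per_class: dict = {}
    f1s = []
    ovr_accs = []
    for lab in labels:
        tp, tn, fp, fn = one_vs_rest_counts(cm, lab, labels)
        sens = _safe_div(tp, tp + fn, f"sensitivity[{lab}]")
        spec = _safe_div(tn, tn + fp, f"specificity[{lab}]")
        prec = _safe_div(tp, tp + fp, f"precision[{lab}]")
        f1 = _safe_div(2 * prec * sens, prec + sens, f"F1[{lab}]")
        acc_i = _safe_div(tp + tn, total, f"accuracy[{lab}]") * 100.0
        per_class[lab] = {
            "tp": tp,
            "tn": tn,
            "fp": fp,
            "fn": fn,
            "sensitivity": sens,
            "recall": sens,
            "specificity": spec,
            "precision": prec,
            "f1": f1,
            "ovr_accuracy_pct": acc_i,
        }
        f1s.append(f1)
        ovr_accs.append(acc_i)
    return ClassMetrics(
        labels=tuple(labels),
        cm=cm,
        per_class=per_class,
        accuracy_pct=_safe_div(float(np.trace(cm)), total, "accuracy") * 100.0,
        macro_ovr_accuracy_pct=float(np.mean(ovr_accs)) if ovr_accs else 0.0,
        macro_f1=float(np.mean(f1s)) if f1s else 0.0,
    )
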