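"""Confusion matrices and one-vs-rest per-class classification metrics.

Per-class metrics collapse all other classes into a single negative class:

    ACC = (TP + TN) / N        RCL = TP / (TP + FN)
    PRC = TP / (TP + FP)       SPC = TN / (TN + FP)
    F1  = 2 * PRC * RCL / (PRC + RCL)

A ratio with a zero denominator is reported as *undefined* (``None``), never
as zero — silent zeros would corrupt downstream decision matrices.  Metric
rows for competing models are assembled into a criteria matrix for EDAS
ranking by :func:`decision_matrix_from_metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from drivestress.edas import DecisionMatrix
from drivestress.errors import EmptyInputError
from drivestress.reference import CRITERIA_WEIGHTS

__all__ = [
    "ConfusionMatrix",
    "MetricsRow",
    "METRIC_NAMES",
    "confusion_matrix",
    "class_metrics",
    "all_class_metrics",
    "overall_accuracy",
    "decision_matrix_from_metrics",
]

METRIC_NAMES = ("ACC", "RCL", "PRC", "F1", "SPC")


@dataclass
class ConfusionMatrix:
    """K×K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K with K = len(class_names)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return len(self.class_names)

    def one_vs_rest(self, k: int):
        """(TP, FP, FN, TN) counts for class index *k*."""
        tp = int(self.counts[k, k])
        fn = int(self.counts[k].sum() - tp)
        fp = int(self.counts[:, k].sum() - tp)
        tn = self.n - tp - fn - fp
        return tp, fp, fn, tn


@dataclass
class MetricsRow:
    """One-vs-rest metrics for one class; ``None`` marks an undefined ratio."""

    acc: float | None
    rcl: float | None
    prc: float | None
    f1: float | None
    spc: float | None

    def as_tuple(self) -> tuple:
        return (self.acc, self.rcl, self.prc, self.f1, self.spc)

    def is_complete(self) -> bool:
        return all(v is not None for v in self.as_tuple())


def confusion_matrix(true, pred, class_names) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a K×K matrix."""
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise ValueError("true and predicted label sequences differ in length")
    if isinstance(class_names, int):
        class_names = tuple(f"class{i}" for i in range(class_names))
    k = len(class_names)
    if len(true) and (true.min() < 0 or true.max() >= k or pred.min() < 0 or pred.max() >= k):
        raise ValueError("labels out of range for the class list")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (true, pred), 1)
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def class_metrics(cm: ConfusionMatrix, k: int) -> MetricsRow:
    """One-vs-rest ACC/RCL/PRC/F1/SPC for class index *k*."""
    tp, fp, fn, tn = cm.one_vs_rest(k)
    acc = _ratio(tp + tn, cm.n)
    rcl = _ratio(tp, tp + fn)
    prc = _ratio(tp, tp + fp)
    spc = _ratio(tn, tn + fp)
    if prc is None or rcl is None or prc + rcl == 0:
        f1 = None
    else:
        f1 = 2 * prc * rcl / (prc + rcl)
    return MetricsRow(acc=acc, rcl=rcl, prc=prc, f1=f1, spc=spc)


def all_class_metrics(cm: ConfusionMatrix) -> dict:
    """Metric rows keyed by class name."""
    return {name: class_metrics(cm, k) for k, name in enumerate(cm.class_names)}


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified instances (trace / N)."""
    if cm.n == 0:
        raise EmptyInputError("confusion matrix has no instances")
    return float(np.trace(cm.counts)) / cm.n


def decision_matrix_from_metrics(rows, weights=None) -> DecisionMatrix:
    """Assemble (model name, MetricsRow) pairs into an EDAS criteria matrix.

    Criteria are ordered (ACC, RCL, PRC, F1, SPC), all flagged beneficial;
    ``weights`` defaults to the bundled reference criteria weights.
    """
    if not rows:
        raise EmptyInputError("no metric rows supplied")
    names, values = [], []
    for name, row in rows:
        if not row.is_complete():
            missing = [m for m, v in zip(METRIC_NAMES, row.as_tuple()) if v is None]
            raise ValueError(f"model {name!r}: undefined metric(s) {missing}")
        names.append(str(name))
        values.append(row.as_tuple())
    w = CRITERIA_WEIGHTS if weights is None else tuple(weights)
    return DecisionMatrix(
        x=np.asarray(values, dtype=float),
        weights=np.asarray(w, dtype=float),
        beneficial=np.ones(len(METRIC_NAMES), dtype=bool),
        names=tuple(names),
        criteria=METRIC_NAMES,
    )
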