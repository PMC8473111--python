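"""Six-class confusion matrices, one-vs-rest metrics, and the data split.

The confusion matrix uses the fixed class order LC, RC, LL, LR, WB, SS with
rows = actual, columns = predicted. Per-class precision and recall come from
the one-vs-rest reduction of the 6x6 matrix:

    Accuracy  = (TP + TN) / (TP + TN + FP + FN)        (one-vs-rest)
    Recall    = TP / (TP + FN)
    Precision = TP / (TP + FP)

Overall accuracy is trace/total of the full matrix; macro averages are
unweighted means over classes. Percentages are printed with two decimals,
rounded half-up, matching the published tables' convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split as _sk_split

from .sensor import POSTURE_CLASSES

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "build_confusion",
    "one_vs_rest",
    "precision_recall_accuracy",
    "train_test_split",
    "round_percent",
]


def round_percent(fraction: float, decimals: int = 2) -> float:
    """Fraction -> percentage rounded half-up (0.9567499 -> 95.67)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """6x6 integer counts; rows = actual class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...] = POSTURE_CLASSES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        n = len(self.class_order)
        if counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    def _index(self, cls: str) -> int:
        try:
            return self.class_order.index(cls)
        except ValueError:
            raise ValueError(f"unknown class {cls!r}") from None

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_table(self) -> str:
        """Printable layout: counts plus Total/Recall column and
        Total/Precision row, percentages at two decimals."""
        report = precision_recall_accuracy(self)
        header = ["", *self.class_order, "Total", "Recall"]
        lines = ["\t".join(header)]
        for i, cls in enumerate(self.class_order):
            row = [cls, *map(str, self.counts[i])]
            row += [str(int(self.counts[i].sum())),
                    f"{round_percent(report.recall[cls]):.2f}%"]
            lines.append("\t".join(row))
        lines.append("\t".join(["Total", *map(str, self.counts.sum(axis=0)), "", ""]))
        lines.append("\t".join(
            ["Precision",
             *(f"{round_percent(report.precision[c]):.2f}%" for c in self.class_order),
             "", ""]))
        return "\n".join(lines)


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and aggregate classification metrics (fractions in [0, 1])."""

    precision: dict[str, float]
    recall: dict[str, float]
    accuracy_ovr: dict[str, float]          # one-vs-rest accuracy per class
    tp_fp_fn_tn: dict[str, tuple[int, int, int, int]]
    overall_accuracy: float                 # trace / total of the 6x6 matrix
    macro_precision: float
    macro_recall: float
    zero_denominator: tuple[str, ...] = ()  # classes where P or R was 0/0

    def as_dict(self) -> dict:
        return {
            "per_class": {
                cls: {"precision": self.precision[cls],
                      "recall": self.recall[cls],
                      "accuracy_ovr": self.accuracy_ovr[cls],
                      "tp_fp_fn_tn": list(self.tp_fp_fn_tn[cls])}
                for cls in self.precision
            },
            "overall_accuracy": self.overall_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "zero_denominator": list(self.zero_denominator),
        }


def build_confusion(actual: Sequence[str], predicted: Sequence[str],
                    class_order: Sequence[str] = POSTURE_CLASSES) -> ConfusionMatrix:
    """Tally (actual, predicted) pairs into a confusion matrix."""
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    order = tuple(class_order)
    index = {c: i for i, c in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise ValueError(f"unknown class in pair ({a!r}, {p!r})")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts, order)


def one_vs_rest(cm: ConfusionMatrix, cls: str) -> tuple[int, int, int, int]:
    """Reduce the 6x6 matrix to (TP, FP, FN, TN) for one class."""
    i = cm._index(cls)
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


def precision_recall_accuracy(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class one-vs-rest metrics plus overall accuracy and macro means.

    A zero denominator (class absent from actual or predicted) yields 0 for
    that metric and the class is listed in ``zero_denominator``.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision, recall, acc_ovr, parts = {}, {}, {}, {}
    flagged = []
    for cls in cm.class_order:
        tp, fp, fn, tn = one_vs_rest(cm, cls)
        parts[cls] = (tp, fp, fn, tn)
        if tp + fp == 0 or tp + fn == 0:
            flagged.append(cls)
        precision[cls] = tp / (tp + fp) if tp + fp else 0.0
        recall[cls] = tp / (tp + fn) if tp + fn else 0.0
        acc_ovr[cls] = (tp + tn) / cm.total
    return MetricsReport(
        precision=precision, recall=recall, accuracy_ovr=acc_ovr,
        tp_fp_fn_tn=parts,
        overall_accuracy=float(np.trace(cm.counts)) / cm.total,
        macro_precision=float(np.mean(list(precision.values()))),
        macro_recall=float(np.mean(list(recall.values()))),
        zero_denominator=tuple(flagged))


def train_test_split(items: Sequence, labels: Sequence[str],
                     train_fraction: float = 0.55, seed: int = 0,
                     ) -> tuple[list, list, list, list]:
    """Stratified, seeded split into (train_items, test_items, train_labels,
    test_labels); the default 55/45 split is the method's evaluation protocol.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = list(labels)
    if len(items) != len(labels):
        raise ValueError("items and labels must have equal length")
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 samples cannot be split: {small}")
    idx_train, idx_test = _sk_split(
        np.arange(len(labels)), train_size=train_fraction, stratify=labels,
        random_state=seed, shuffle=True)
    items = list(items)
    return ([items[i] for i in idx_train], [items[i] for i in idx_test],
            [labels[i] for i in idx_train], [labels[i] for i in idx_test])
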