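"""Confusion matrix and the metric suite: accuracy, macro recall/precision/F1
and two kappa conventions.

``kappa_paper`` uses observed agreement p0 = overall accuracy and a chance
agreement derived from pooling the K one-vs-rest binary tables: each pooled
table has N positives and (K-1)N negatives on both margins, so
pe = (N^2 + ((K-1)N)^2) / (KN)^2 = (1 + (K-1)^2) / K^2 regardless of the
matrix contents.  For K = 3 this gives pe = 5/9 and the closed form
kappa = (9*p0 - 5)/4.  Standard Cohen's kappa (chance agreement from the
row/column marginals of the actual matrix) is reported alongside.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .dataset import CLASSES


def round_percent(x: float, ndigits: int = 2) -> float:
    """Half-up rounding of a fraction onto the percent scale (0.972222 -> 97.22)."""
    return float(
        Decimal(repr(float(x) * 100.0)).quantize(
            Decimal("1." + "0" * ndigits), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        K = len(self.classes)
        if self.counts.shape != (K, K):
            raise ValueError(f"counts must be {K}x{K} for classes {self.classes}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, i: int) -> dict[str, int]:
        """TP/FP/TN/FN marginalization for class i."""
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return {"TP": tp, "FP": fp, "TN": tn, "FN": fn}


@dataclass
class MetricsReport:
    accuracy: float
    per_class_recall: np.ndarray
    per_class_precision: np.ndarray
    per_class_f1: np.ndarray
    macro_recall: float
    macro_precision: float
    macro_f1: float
    p0: float
    pe_paper: float
    kappa_paper: float
    kappa_cohen: float
    confusion: ConfusionMatrix | None = None

    def as_percent_strings(self) -> dict[str, str]:
        """Printed-style 2-dp percentage renderings of the macro metrics."""
        return {
            "accuracy": f"{round_percent(self.accuracy):.2f}",
            "recall": f"{round_percent(self.macro_recall):.2f}",
            "precision": f"{round_percent(self.macro_precision):.2f}",
            "f1": f"{round_percent(self.macro_f1):.2f}",
            "kappa": f"{round_percent(self.kappa_paper):.2f}",
        }

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "per_class_recall": self.per_class_recall.tolist(),
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_f1": self.per_class_f1.tolist(),
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "p0": self.p0,
            "pe_paper": self.pe_paper,
            "kappa_paper": self.kappa_paper,
            "kappa_cohen": self.kappa_cohen,
            "percent": self.as_percent_strings(),
        }
        if self.confusion is not None:
            d["confusion_matrix"] = self.confusion.counts.tolist()
            d["classes"] = list(self.confusion.classes)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confusion(y_true, y_pred, classes: tuple = CLASSES) -> ConfusionMatrix:
    """Count matrix in a fixed class order (NM, SH, MD by default)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    unknown = (set(y_true) | set(y_pred)) - set(classes)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(map(str, unknown))}")
    counts = _sk_confusion(y_true, y_pred, labels=list(classes))
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


def pooled_chance_agreement(n_classes: int) -> float:
    """Chance agreement of the pooled one-vs-rest marginals: (1+(K-1)^2)/K^2."""
    return (1.0 + (n_classes - 1) ** 2) / n_classes**2


def kappa_from_accuracy(p0: float, n_classes: int) -> float:
    """Paper-convention kappa given only the overall accuracy."""
    pe = pooled_chance_agreement(n_classes)
    return (p0 - pe) / (1.0 - pe)


def report(cm: ConfusionMatrix) -> MetricsReport:
    """Full metric suite from a confusion matrix."""
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    K = len(cm.classes)
    counts = cm.counts.astype(float)
    accuracy = float(np.trace(counts)) / cm.total

    recalls, precisions, f1s = [], [], []
    for i in range(K):
        m = cm.one_vs_rest(i)
        rec = m["TP"] / (m["TP"] + m["FN"]) if m["TP"] + m["FN"] > 0 else 0.0
        if m["TP"] + m["FP"] == 0:
            warnings.warn(
                f"class {cm.classes[i]!r} has zero predicted positives; "
                "precision defined as 0",
                UserWarning,
            )
            prec = 0.0
        else:
            prec = m["TP"] / (m["TP"] + m["FP"])
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        recalls.append(rec)
        precisions.append(prec)
        f1s.append(f1)

    pe_paper = pooled_chance_agreement(K)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    pe_cohen = float(np.sum(row * col)) / cm.total**2
    kappa_cohen = (
        (accuracy - pe_cohen) / (1.0 - pe_cohen) if pe_cohen < 1.0 else 1.0
    )

    return MetricsReport(
        accuracy=accuracy,
        per_class_recall=np.array(recalls),
        per_class_precision=np.array(precisions),
        per_class_f1=np.array(f1s),
        macro_recall=float(np.mean(recalls)),
        macro_precision=float(np.mean(precisions)),
        macro_f1=float(np.mean(f1s)),
        p0=accuracy,
        pe_paper=pe_paper,
        kappa_paper=kappa_from_accuracy(accuracy, K),
        kappa_cohen=kappa_cohen,
        confusion=cm,
    )


def total_from_per_class(per_class_accuracy, class_sizes) -> float:
    """Size-weighted overall accuracy from per-class accuracies.

    Per-class accuracies are first converted back to integer correct counts
    (round-half-up of acc * size), matching how per-class percentages arise
    from counted test samples.  Accepts fractions in [0, 1] or percentages
    (detected by values above 1) and answers on the same scale, e.g.
    (100.00, 95.60, 72.41) with sizes (60, 91, 29) gives 93.33.
    """
    accs = np.asarray(per_class_accuracy, dtype=float)
    sizes = np.asarray(class_sizes, dtype=float)
    if accs.shape != sizes.shape:
        raise ValueError("per_class_accuracy and class_sizes must align")
    if (sizes <= 0).any():
        raise ValueError("class sizes must be positive")
    percent_scale = bool(np.any(accs > 1.0))
    frac = accs / 100.0 if percent_scale else accs
    correct = np.floor(frac * sizes + 0.5)
    total = float(correct.sum() / sizes.sum())
    return total * 100.0 if percent_scale else total
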