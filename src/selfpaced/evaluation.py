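"""Evaluation surface: confusion matrices, P/R/F1, repeat summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

__all__ = [
    "ConfusionMatrix",
    "ClassificationReport",
    "confusion_matrix",
    "precision_recall_f1",
    "summarize_repeats",
    "format_mean_sd",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """C×C count matrix; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_names: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        names = self.class_names
        if names is None:
            names = [str(i) for i in range(counts.shape[0])]
        elif len(names) != counts.shape[0]:
            raise ValueError("class_names length must match matrix size")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_names", list(names))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            return float("nan")
        return float(np.trace(self.counts) / self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"true_{n}" for n in self.class_names],
            columns=[f"pred_{n}" for n in self.class_names],
        )

    def render(self) -> str:
        """Plain-text rendering for logs."""
        return self.to_frame().to_string()


def confusion_matrix(y_true, y_pred, n_classes: int, class_names=None) -> ConfusionMatrix:
    """Build a confusion matrix over ``n_classes`` classes."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if y_true.size == 0:
        counts = np.zeros((n_classes, n_classes), dtype=int)
    else:
        counts = _sk_confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionMatrix(counts=counts, class_names=class_names)


@dataclass(frozen=True)
class ClassificationReport:
    """Per-class and macro-averaged precision/recall/F1.

    ``degenerate`` flags classes whose precision or recall denominator was
    zero (metric reported as 0).
    """

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro: dict
    weighted: dict
    accuracy: float
    degenerate: np.ndarray

    def to_dict(self) -> dict:
        return {
            "per_class": {
                "precision": [float(v) for v in self.precision],
                "recall": [float(v) for v in self.recall],
                "f1": [float(v) for v in self.f1],
                "support": [int(v) for v in self.support],
            },
            "macro": self.macro,
            "weighted": self.weighted,
            "accuracy": self.accuracy,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
            }
        )


def _safe_div(num, den, flag):
    out = np.zeros_like(num, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    flag |= ~ok
    return out


def precision_recall_f1(M: ConfusionMatrix) -> ClassificationReport:
    """Per-class and averaged metrics from a confusion matrix.

    For class ``c``: precision = TP/(TP+FP) down the column, recall =
    TP/(TP+FN) along the row, F1 their harmonic mean.  A zero denominator
    yields 0 and sets the class's degenerate flag.  The macro average is
    unweighted over classes (imbalance-sensitive); a support-weighted
    average is also reported.
    """
    counts = M.counts
    if counts.sum() == 0:
        raise ValueError("cannot compute metrics from an empty confusion matrix")
    tp = np.diag(counts).astype(float)
    support = counts.sum(axis=1)
    predicted = counts.sum(axis=0)
    degenerate = np.zeros(M.n_classes, dtype=bool)
    precision = _safe_div(tp, predicted.astype(float), degenerate)
    recall = _safe_div(tp, support.astype(float), degenerate)
    f1 = _safe_div(2 * precision * recall, precision + recall, degenerate)
    weights = support / support.sum()
    macro = {
        "precision": float(precision.mean()),
        "recall": float(recall.mean()),
        "f1": float(f1.mean()),
    }
    weighted = {
        "precision": float(precision @ weights),
        "recall": float(recall @ weights),
        "f1": float(f1 @ weights),
    }
    return ClassificationReport(
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        macro=macro,
        weighted=weighted,
        accuracy=M.accuracy,
        degenerate=degenerate,
    )


def format_mean_sd(mean: float, sd: float, decimals: int = 2) -> str:
    return f"{mean:.{decimals}f} ± {sd:.{decimals}f}"


def summarize_repeats(reports: list) -> dict:
    """Mean ± sample standard deviation per metric across repeated runs.

    Every report must carry the same scalar metric keys.  The standard
    deviation uses the n−1 denominator; a single report yields sd 0.
    Returns ``{metric: {"mean": m, "sd": s, "formatted": "m ± s"}}``.
    """
    if not reports:
        raise ValueError("need at least one report")
    keys = list(reports[0])
    for rep in reports[1:]:
        if list(rep) != keys:
            raise ValueError("reports carry inconsistent metric keys")
    out = {}
    for key in keys:
        vals = np.array([float(rep[key]) for rep in reports])
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[key] = {"mean": mean, "sd": sd, "formatted": format_mean_sd(mean, sd)}
    return out
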