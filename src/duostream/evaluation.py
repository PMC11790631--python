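"""Classification metrics: accuracy, macro recall, macro F1, inter-class
stability (std of per-class recall, in percentage points), parameter count,
average inference time, and the confusion matrix.

Macro (unweighted) class averaging is the default; weighted averaging is
available behind a flag.  The inter-class STD uses the population
denominator and is reported in percentage points, matching how stability is
usually tabulated alongside Acc/Recall/F1 percentages.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EvalReport:
    accuracy: float
    recall_macro: float
    f1_macro: float
    std_between_classes: float  # percentage points
    param_count: int = 0
    avg_inference_time: float = float("nan")  # seconds per sample
    confusion: np.ndarray | None = None
    classes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "std_between_classes": self.std_between_classes,
            "param_count": self.param_count,
            "avg_inference_time": self.avg_inference_time,
            "classes": list(self.classes),
            "confusion": None if self.confusion is None else self.confusion.tolist(),
        }

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.classes, columns=self.classes)


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    """Count matrix: entry (i, j) = true class i predicted as class j.

    Rows/columns follow the given class ordering.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(y_true) | set(y_pred)) - set(index)
    if unknown:
        raise ValueError(f"labels not in class list: {sorted(map(str, unknown))}")
    m = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        m[index[t], index[p]] += 1
    return m


def compute_metrics(confusion: np.ndarray, average: str = "macro"):
    """(accuracy, recall, f1, std_between_classes) from a count matrix.

    Per-class recall = diag/rowsum, precision = diag/colsum (0 on empty
    columns); recall/F1 are class means (unweighted for ``macro``, test-count
    weighted for ``weighted``); std_between_classes is the population std of
    per-class recall in percentage points.
    """
    m = np.asarray(confusion)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(m < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    row = m.sum(axis=1).astype(np.float64)
    col = m.sum(axis=0).astype(np.float64)
    if np.any(row == 0):
        raise ValueError("every class needs at least one true sample")
    total = m.sum()
    diag = np.diag(m).astype(np.float64)
    accuracy = float(diag.sum() / total)
    recall = diag / row
    precision = np.divide(diag, col, out=np.zeros_like(diag), where=col > 0)
    denom = precision + recall
    f1 = np.divide(2 * precision * recall, denom, out=np.zeros_like(diag), where=denom > 0)
    if average == "macro":
        weights = np.full(len(row), 1.0 / len(row))
    elif average == "weighted":
        weights = row / row.sum()
    else:
        raise ValueError(f"unknown average {average!r}")
    recall_mean = float(recall @ weights)
    f1_mean = float(f1 @ weights)
    std_points = float(np.std(recall) * 100.0)  # population std, percentage points
    return accuracy, recall_mean, f1_mean, std_points


def evaluate_predictions(y_true, y_pred, classes, average: str = "macro") -> EvalReport:
    m = confusion_matrix(y_true, y_pred, classes)
    acc, rec, f1, std = compute_metrics(m, average=average)
    return EvalReport(
        accuracy=acc,
        recall_macro=rec,
        f1_macro=f1,
        std_between_classes=std,
        confusion=m,
        classes=list(classes),
    )


def measure_inference_time(model, sample_pairs, n_warmup: int = 2, n_timed: int = 10) -> float:
    """Mean single-sample forward wall-clock time (batch size 1), in seconds.

    ``sample_pairs`` is a sequence of preprocessed :class:`ViewPair`-like
    objects cycled through; the first ``n_warmup`` calls are discarded.
    """
    from .model import classify

    if n_timed < 1:
        raise ValueError("n_timed must be >= 1")
    pairs = list(sample_pairs)
    if not pairs:
        raise ValueError("need at least one sample pair")
    for i in range(n_warmup):
        classify(model, pairs[i % len(pairs)])
    times = []
    for i in range(n_timed):
        t0 = time.perf_counter()
        classify(model, pairs[i % len(pairs)])
        times.append(time.perf_counter() - t0)
    return float(np.mean(times))
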