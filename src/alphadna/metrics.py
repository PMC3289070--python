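"""Confusion-matrix construction and the five performance measures.

Recall, Specificity, Precision, Accuracy and the Matthews correlation
coefficient, with +1 meaning DNA-binding.  Ratios with a zero
denominator are reported as NaN with a warning; the MCC convention
maps a zero denominator to 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "metrics", "confusion_from_predictions", "report_table"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning, stacklevel=3)
        return math.nan
    return num / den


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """The five measures as fractions (MCC in [-1, 1])."""
    mcc_den = math.sqrt(
        float(cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    return {
        "recall": _ratio(cm.tp, cm.tp + cm.fn, "recall"),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        "precision": _ratio(cm.tp, cm.tp + cm.fp, "precision"),
        "accuracy": _ratio(cm.tp + cm.tn, cm.total, "accuracy"),
        "mcc": 0.0 if mcc_den == 0 else (cm.tp * cm.tn - cm.fp * cm.fn) / mcc_den,
    }


def confusion_from_predictions(labels_true, labels_pred) -> ConfusionMatrix:
    """Count TP/FP/TN/FN from +1/-1 label arrays."""
    yt = np.asarray(labels_true, dtype=int)
    yp = np.asarray(labels_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("label arrays must have equal length")
    for arr in (yt, yp):
        if not set(np.unique(arr)) <= {-1, 1}:
            raise ValueError("labels must be +1 / -1")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == -1) & (yp == 1))),
        tn=int(np.sum((yt == -1) & (yp == -1))),
        fn=int(np.sum((yt == 1) & (yp == -1))),
    )


def report_table(rows: dict[str, ConfusionMatrix]) -> pd.DataFrame:
    """Benchmark-style report: percentages to 2 dp, MCC to 4 dp."""
    records = []
    for name, cm in rows.items():
        m = metrics(cm)
        records.append(
            {
                "Method": name,
                "Recall": round(100 * m["recall"], 2),
                "Specificity": round(100 * m["specificity"], 2),
                "Precision": round(100 * m["precision"], 2),
                "Accuracy": round(100 * m["accuracy"], 2),
                "MCC": round(m["mcc"], 4),
            }
        )
    return pd.DataFrame.from_records(records)
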