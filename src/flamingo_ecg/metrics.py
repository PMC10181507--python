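"""Confusion matrix and accuracy / sensitivity / specificity reporting.

Accuracy = (TP + TN) / (TP + TN + FP + FN), sensitivity = TP / (TP + FN),
specificity = TN / (TN + FP). The three are binary notions; for the
five-class beat task each class is scored one-vs-rest and the metrics are
macro-averaged (``mode="macro"``), or the task is collapsed to
normal-vs-abnormal first (``mode="binary"`` on a 2-class matrix, scored on
the positive = second class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "compute_metrics",
    "collapse_binary",
]


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K class names")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names),
                            columns=list(self.class_names))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class MetricsReport:
    """Fractions in [0, 1]; ``as_percent`` formats them the way tables print."""

    accuracy: float
    sensitivity: float
    specificity: float
    mode: str
    per_class: dict

    def as_percent(self, decimals: int = 2) -> dict:
        return {
            "accuracy": round(100.0 * self.accuracy, decimals),
            "sensitivity": round(100.0 * self.sensitivity, decimals),
            "specificity": round(100.0 * self.specificity, decimals),
        }


def confusion_matrix(true_labels, predicted_labels, class_names) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if true_labels.size != predicted_labels.size:
        raise ValueError("true and predicted label arrays differ in length")
    lookup = {c: i for i, c in enumerate(class_names)}
    k = len(class_names)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in lookup:
            raise ValueError(f"unknown true label {t!r}")
        if p not in lookup:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[lookup[t], lookup[p]] += 1
    return ConfusionMatrix(counts, tuple(class_names))


def _one_vs_rest(cm: ConfusionMatrix, i: int) -> dict:
    c = cm.counts
    tp = int(c[i, i])
    fn = int(c[i].sum() - tp)
    fp = int(c[:, i].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}


def compute_metrics(cm: ConfusionMatrix, mode: str = "macro") -> MetricsReport:
    """Score a confusion matrix.

    ``macro``: one-vs-rest per class, metrics averaged over classes where
    they are defined (division-by-zero classes are dropped with a warning).
    ``binary``: requires K = 2; the second class is the positive one.
    """
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    per_class = {name: _one_vs_rest(cm, i) for i, name in enumerate(cm.class_names)}
    accuracy = float(np.trace(cm.counts)) / cm.total
    if mode == "binary":
        if len(cm.class_names) != 2:
            raise ValueError("binary mode requires a 2-class confusion matrix")
        d = per_class[cm.class_names[1]]
        sens = d["TP"] / (d["TP"] + d["FN"]) if d["TP"] + d["FN"] else float("nan")
        spec = d["TN"] / (d["TN"] + d["FP"]) if d["TN"] + d["FP"] else float("nan")
        return MetricsReport(accuracy, sens, spec, "binary", per_class)
    if mode != "macro":
        raise ValueError("mode must be 'macro' or 'binary'")
    sens_list, spec_list, dropped = [], [], []
    for name, d in per_class.items():
        if d["TP"] + d["FN"] > 0:
            sens_list.append(d["TP"] / (d["TP"] + d["FN"]))
        else:
            dropped.append(name)
        if d["TN"] + d["FP"] > 0:
            spec_list.append(d["TN"] / (d["TN"] + d["FP"]))
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(
            f"metric undefined for class(es) {sorted(set(dropped))}; "
            "macro average taken over defined classes",
            stacklevel=2,
        )
    sens = float(np.mean(sens_list)) if sens_list else float("nan")
    spec = float(np.mean(spec_list)) if spec_list else float("nan")
    return MetricsReport(accuracy, sens, spec, "macro", per_class)


def collapse_binary(labels, normal_class: str = "N"):
    """Collapse five-class labels to normal-vs-abnormal for the binary reading."""
    labels = np.asarray(labels, dtype=object)
    return np.where(labels == normal_class, "normal", "abnormal").astype(object)
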