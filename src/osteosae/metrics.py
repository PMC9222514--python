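"""Per-class and macro-averaged evaluation of a multiclass classifier.

Each class is scored through its one-vs-rest reduction of the confusion
matrix: accuracy, precision, recall, F-score, Matthews correlation (MCC) and
the geometric mean of sensitivity and specificity (G-mean).  All values are
reported as percentages; an unweighted Average row summarises the classes.

Zero-denominator conventions: F-score, MCC and G-mean return 0 when their
denominators vanish.  Two-decimal rounding is presentation-only — the CSV
report keeps full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "confusion_from_predictions",
    "one_vs_rest",
    "f_score",
    "mcc",
    "g_mean",
    "per_class_accuracy",
    "precision_pct",
    "recall_pct",
    "class_metrics_table",
    "macro_average",
    "render_report",
]

METRIC_COLUMNS = ["accuracy", "precision", "recall", "f_score", "mcc", "g_mean"]


@dataclass
class ConfusionMatrix:
    """C x C counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.class_names = tuple(self.class_names)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] != len(self.class_names):
            raise ValueError("class_names length must match matrix size")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names), columns=list(self.class_names))


def confusion_from_predictions(
    y_true: Sequence, y_pred: Sequence, class_names: Sequence[str]
) -> ConfusionMatrix:
    """Tally a confusion matrix from label sequences (labels or class indices)."""
    names = list(class_names)
    idx = {c: i for i, c in enumerate(names)}
    counts = np.zeros((len(names), len(names)), dtype=np.int64)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    for t, p in zip(y_true, y_pred):
        ti = t if isinstance(t, (int, np.integer)) else idx[t]
        pi = p if isinstance(p, (int, np.integer)) else idx[p]
        counts[ti, pi] += 1
    return ConfusionMatrix(counts, tuple(names))


def one_vs_rest(cm: ConfusionMatrix, class_index: int) -> tuple[int, int, int, int]:
    """Binary (TP, FP, FN, TN) counts for one class against all others."""
    c = cm.counts
    if not 0 <= class_index < c.shape[0]:
        raise IndexError(f"class index {class_index} out of range")
    tp = int(c[class_index, class_index])
    fp = int(c[:, class_index].sum() - tp)
    fn = int(c[class_index, :].sum() - tp)
    tn = int(c.sum() - tp - fp - fn)
    return tp, fp, fn, tn


def f_score(precision_pct_: float, recall_pct_: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision_pct_ + recall_pct_ <= 0:
        return 0.0
    return 2.0 * precision_pct_ * recall_pct_ / (precision_pct_ + recall_pct_)


def mcc(TP: int, FP: int, FN: int, TN: int) -> float:
    """Matthews correlation of the binary reduction, as a percentage in [-100, 100]."""
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    if denom == 0:
        return 0.0
    return 100.0 * (TP * TN - FP * FN) / math.sqrt(denom)


def g_mean(TP: int, FP: int, FN: int, TN: int) -> float:
    """100 * sqrt(sensitivity * specificity); 0 when either denominator vanishes."""
    if TP + FN == 0 or TN + FP == 0:
        return 0.0
    sens = TP / (TP + FN)
    spec = TN / (TN + FP)
    return 100.0 * math.sqrt(sens * spec)


def per_class_accuracy(TP: int, FP: int, FN: int, TN: int) -> float:
    """One-vs-rest accuracy 100 * (TP + TN) / total."""
    total = TP + FP + FN + TN
    if total == 0:
        raise ValueError("empty confusion counts")
    return 100.0 * (TP + TN) / total


def precision_pct(TP: int, FP: int) -> float:
    return 0.0 if TP + FP == 0 else 100.0 * TP / (TP + FP)


def recall_pct(TP: int, FN: int) -> float:
    return 0.0 if TP + FN == 0 else 100.0 * TP / (TP + FN)


def class_metrics_table(cm: ConfusionMatrix) -> pd.DataFrame:
    """Full-precision per-class metric rows plus an Average row.

    Columns follow the standard report order: accuracy, precision, recall,
    f_score, mcc, g_mean (all percentages).
    """
    rows = []
    for i, name in enumerate(cm.class_names):
        tp, fp, fn, tn = one_vs_rest(cm, i)
        p = precision_pct(tp, fp)
        r = recall_pct(tp, fn)
        rows.append(
            {
                "class": name,
                "accuracy": per_class_accuracy(tp, fp, fn, tn),
                "precision": p,
                "recall": r,
                "f_score": f_score(p, r),
                "mcc": mcc(tp, fp, fn, tn),
                "g_mean": g_mean(tp, fp, fn, tn),
            }
        )
    table = pd.DataFrame(rows).set_index("class")
    table.loc["Average"] = macro_average(table)
    return table


def macro_average(table: pd.DataFrame) -> pd.Series:
    """Unweighted arithmetic mean of the per-class rows (Average row)."""
    per_class = table.loc[[i for i in table.index if i != "Average"]]
    return per_class.mean(axis=0)


def render_report(cm: ConfusionMatrix, out_dir: str | Path | None = None, name: str = "metrics"):
    """Produce the metric table and, optionally, CSV + Markdown renderings.

    The CSV keeps full precision; the Markdown shows the conventional
    two-decimal presentation.  Returns the full-precision DataFrame.
    """
    table = class_metrics_table(cm)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / f"{name}.csv")
        cm.to_frame().to_csv(out / f"{name}_confusion.csv")
        (out / f"{name}.md").write_text(_to_markdown(table))
    return table


def _to_markdown(table: pd.DataFrame) -> str:
    header = ["Class Labels"] + [c.replace("_", "-").title() for c in table.columns]
    lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    for idx, row in table.iterrows():
        lines.append("| " + " | ".join([str(idx)] + [f"{v:.2f}" for v in row]) + " |")
    return "\n".join(lines) + "\n"
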