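"""Published benchmark results for the osteosarcoma patch classifier.

The study this package re-implements reported per-class evaluation tables on
an external osteosarcoma histology benchmark (1144 patches: 345 viable tumor,
263 non-viable tumor, 536 non-tumor) under 80/20 and 70/30 train/test splits.
The raw benchmark is not redistributed here; the printed tables are kept as
data because parts of them are internally derivable — the F-score from the
precision/recall pair of the same row, and each Average cell from its three
per-class cells — which makes them a useful end-to-end consistency check of
the metric arithmetic in :mod:`osteosae.metrics`.

Values are percentages at the two-decimal precision of the original report.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_tables", "fscore_deviations", "average_deviations"]

_COLUMNS = ["accuracy", "precision", "recall", "f_score", "mcc", "g_mean"]

# split -> phase -> class -> [accuracy, precision, recall, f_score, mcc, g_mean]
_PUBLISHED = {
    "80/20": {
        "train": {
            "VT": [99.45, 98.49, 99.62, 99.05, 98.67, 99.50],
            "NVT": [98.91, 97.71, 97.71, 97.71, 96.99, 98.49],
            "NT": [98.36, 98.61, 97.93, 98.27, 96.71, 98.34],
            "Average": [98.91, 98.27, 98.42, 98.34, 97.46, 98.78],
        },
        "test": {
            "VT": [100.00, 100.00, 100.00, 100.00, 100.00, 100.00],
            "NVT": [99.56, 97.83, 100.00, 98.90, 98.64, 99.73],
            "NT": [99.56, 100.00, 99.01, 99.50, 99.12, 99.50],
            "Average": [99.71, 99.28, 99.67, 99.47, 99.25, 99.74],
        },
    },
    "70/30": {
        "train": {
            "VT": [99.00, 98.30, 98.30, 98.30, 97.59, 98.79],
            "NVT": [99.25, 99.43, 97.19, 98.30, 97.83, 98.51],
            "NT": [99.00, 98.47, 99.48, 98.97, 98.00, 99.01],
            "Average": [99.08, 98.73, 98.32, 98.52, 97.81, 98.77],
        },
        "test": {
            "VT": [99.42, 99.09, 99.09, 99.09, 98.66, 99.33],
            "NVT": [99.13, 98.81, 97.65, 98.22, 97.65, 98.63],
            "NT": [99.13, 98.67, 99.33, 99.00, 98.23, 99.15],
            "Average": [99.22, 98.86, 98.69, 98.77, 98.18, 99.04],
        },
    },
}


def published_tables() -> dict[str, dict[str, pd.DataFrame]]:
    """The published per-class metric tables, as DataFrames keyed split -> phase."""
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for split, phases in _PUBLISHED.items():
        out[split] = {
            phase: pd.DataFrame.from_dict(rows, orient="index", columns=_COLUMNS)
            for phase, rows in phases.items()
        }
    return out


def fscore_deviations() -> pd.Series:
    """Printed F-score minus the F-score recomputed from the printed (P, R) pair.

    One entry per class row of every published table; values within the
    two-decimal rounding of the printed cells (|dev| <= 0.01 plus rounding of
    the inputs) confirm that the harmonic-mean definition in
    :func:`osteosae.metrics.f_score` matches the published arithmetic.
    """
    from .metrics import f_score

    devs = {}
    for split, phases in _PUBLISHED.items():
        for phase, rows in phases.items():
            for cls, vals in rows.items():
                if cls == "Average":
                    continue
                _, p, r, f, _, _ = vals
                devs[f"{split}/{phase}/{cls}"] = f - f_score(p, r)
    return pd.Series(devs, name="fscore_deviation")


def average_deviations() -> pd.Series:
    """Printed Average cell minus the mean of its three printed per-class cells."""
    devs = {}
    for split, phases in _PUBLISHED.items():
        for phase, rows in phases.items():
            classes = [c for c in rows if c != "Average"]
            for j, col in enumerate(_COLUMNS):
                mean = sum(rows[c][j] for c in classes) / len(classes)
                devs[f"{split}/{phase}/{col}"] = rows["Average"][j] - mean
    return pd.Series(devs, name="average_deviation")
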