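"""Confusion-matrix construction and the ten-metric evaluation report.

Counts follow the artifact-wide convention hb = true positives, hc = true
negatives, hd = false positives, he = false negatives. All metrics are
reported on the 0-100 scale (MCC is the coefficient scaled by 100, so it lies
in [-100, 100]). A metric with a zero denominator is reported as ``None``
(serialized as JSON null) and listed in the report's ``undefined`` field,
never silently as 0.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, fields

import numpy as np

METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "FPR",
    "FNR",
    "NPV",
    "FDR",
    "F1",
    "MCC",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    hb: int  # true positives
    hc: int  # true negatives
    hd: int  # false positives
    he: int  # false negatives

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {f.name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.hb + self.hc + self.hd + self.he

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.hb + other.hb, self.hc + other.hc, self.hd + other.hd, self.he + other.he
        )


@dataclass
class MetricReport:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    FPR: float | None
    FNR: float | None
    NPV: float | None
    FDR: float | None
    F1: float | None
    MCC: float | None
    undefined: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/TN/FP/FN for binary label vectors (positive class = 1)."""
    y_true = np.asarray(y_true).reshape(-1)
    y_pred = np.asarray(y_pred).reshape(-1)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape[0]} vs {y_pred.shape[0]}")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1 values")
    return ConfusionMatrix(
        hb=int(np.sum((y_true == 1) & (y_pred == 1))),
        hc=int(np.sum((y_true == 0) & (y_pred == 0))),
        hd=int(np.sum((y_true == 0) & (y_pred == 1))),
        he=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Derive the ten performance metrics from the confusion counts.

    accuracy=(hb+hc)/n, sensitivity=hb/(hb+he), specificity=hc/(hc+hd),
    precision=hb/(hb+hd), NPV=hc/(hc+he), FPR=hd/(hd+hc), FNR=he/(he+hb),
    FDR=hd/(hd+hb), F1=2hb/(2hb+hd+he), and the Matthews correlation
    coefficient — all scaled by 100.
    """
    hb, hc, hd, he = cm.hb, cm.hc, cm.hd, cm.he
    mcc_den = math.sqrt((hb + hd) * (hb + he) * (hc + hd) * (hc + he))
    vals = {
        "accuracy": _ratio(hb + hc, cm.n),
        "sensitivity": _ratio(hb, hb + he),
        "specificity": _ratio(hc, hc + hd),
        "precision": _ratio(hb, hb + hd),
        "FPR": _ratio(hd, hd + hc),
        "FNR": _ratio(he, he + hb),
        "NPV": _ratio(hc, hc + he),
        "FDR": _ratio(hd, hd + hb),
        "F1": _ratio(2 * hb, 2 * hb + hd + he),
        "MCC": None if mcc_den == 0 else 100.0 * (hb * hc - hd * he) / mcc_den,
    }
    return MetricReport(**vals, undefined=[k for k, v in vals.items() if v is None])


def evaluate(y_true, y_pred) -> MetricReport:
    return compute_metrics(confusion(y_true, y_pred))


def kfold_evaluate(runner, df, k: int = 5, seed: int = 0):
    """Run a train/predict chain per fold and report per-fold plus pooled metrics.

    ``runner(train_df, test_df) -> y_pred`` must fit on the training fold only.
    The pooled report is computed from the summed confusion counts. Returns
    ``(fold_reports, pooled_report, pooled_cm)``.
    """
    from .data import kfold_split

    folds = kfold_split(len(df), k, seed)
    reports, total = [], ConfusionMatrix(0, 0, 0, 0)
    for i, (tr, te) in enumerate(folds):
        train_df = df.iloc[tr].reset_index(drop=True)
        test_df = df.iloc[te].reset_index(drop=True)
        try:
            y_pred = runner(train_df, test_df)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed in fold {i}: {exc}") from exc
        cm = confusion(test_df["label"].to_numpy(), np.asarray(y_pred))
        reports.append(compute_metrics(cm))
        total = total + cm
    return reports, compute_metrics(total), total


def holdout_evaluate(runner, df, percent: float = 70.0, seed: int = 0):
    """Single learning-percentage split: train on ``percent`` % of the
    records, evaluate on the rest. Returns ``(report, cm)``."""
    from .data import learning_percentage_split

    tr, te = learning_percentage_split(len(df), percent, seed)
    train_df = df.iloc[tr].reset_index(drop=True)
    test_df = df.iloc[te].reset_index(drop=True)
    y_pred = runner(train_df, test_df)
    cm = confusion(test_df["label"].to_numpy(), np.asarray(y_pred))
    return compute_metrics(cm), cm


def write_report(reports: dict, path_base) -> None:
    """Persist named reports as ``<base>.json`` and ``<base>.csv``.

    One row per metric, one column per configuration; undefined metrics are
    JSON null / empty CSV cells.
    """
    path_base = str(path_base)
    payload = {name: rep.as_dict() for name, rep in reports.items()}
    with open(path_base + ".json", "w") as fh:
        json.dump(payload, fh, indent=2)
    with open(path_base + ".csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        names = list(reports)
        writer.writerow(["Measures", *names])
        for metric in METRIC_NAMES:
            writer.writerow(
                [metric]
                + [
                    "" if payload[n][metric] is None else f"{payload[n][metric]:.2f}"
                    for n in names
                ]
            )


def read_report(path_json) -> dict:
    with open(path_json) as fh:
        payload = json.load(fh)
    return {
        name: MetricReport(
            **vals, undefined=[k for k, v in vals.items() if v is None]
        )
        for name, vals in payload.items()
    }
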