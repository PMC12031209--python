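"""Evaluation metrics for the joint recognition + regression task.

Classification metrics are computed from the argmax of the softmax output
with macro averaging over the three classes (single n-propanol, single
ethanol, mixture); per-class AUC is one-vs-rest on the softmax scores and
reported as NaN (undefined) when a class is absent from the test set.
Regression metrics pool both gas targets: MAE is the mean absolute error in
ppm over both columns, and R^2 = 1 - sum(SS_res) / sum(SS_tot) with
per-target means (equivalently, a variance-weighted average of per-target
R^2 scores).  Per-gas values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support, roc_auc_score)

from .simulate import CLASS_NAMES


@dataclass
class MetricsReport:
    """Metric suite for one evaluation (e.g. one CV fold)."""

    n: int
    accuracy: float = np.nan
    precision: float = np.nan
    recall: float = np.nan
    f1: float = np.nan
    confusion: np.ndarray | None = None          # (3, 3), rows = true class
    auc_per_class: dict[str, float] = field(default_factory=dict)
    mae: float = np.nan                          # ppm, pooled over both gases
    mae_per_gas: dict[str, float] = field(default_factory=dict)
    r2: float = np.nan                           # pooled over both gases
    r2_per_gas: dict[str, float] = field(default_factory=dict)

    def scalars(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "mae": self.mae, "r2": self.r2}

    def to_dict(self) -> dict:
        out = {"n": self.n, **self.scalars()}
        out["confusion"] = None if self.confusion is None else self.confusion.tolist()
        out["auc_per_class"] = self.auc_per_class
        out["mae_per_gas"] = self.mae_per_gas
        out["r2_per_gas"] = self.r2_per_gas
        return out


def pooled_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """1 - sum of residual squares over sum of total squares, both summed
    across target columns (per-column means)."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    ss_res = ((y_true - y_pred) ** 2).sum()
    ss_tot = ((y_true - y_true.mean(axis=0)) ** 2).sum()
    if ss_tot == 0:
        return np.nan
    return 1.0 - ss_res / ss_tot


def compute_metrics(
    y_class: np.ndarray | None,
    class_probs: np.ndarray | None,
    y_conc: np.ndarray | None = None,
    conc_pred: np.ndarray | None = None,
    gas_names: tuple[str, str] = ("propanol", "ethanol"),
) -> MetricsReport:
    """Assemble the full metric suite from predictions.

    Either task may be absent (single-task models); its metrics stay NaN.
    """
    n = len(y_class) if y_class is not None else len(y_conc)
    report = MetricsReport(n=n)
    labels = list(range(len(CLASS_NAMES)))

    if y_class is not None and class_probs is not None:
        if len(y_class) == 0:
            raise ValueError("empty test set")
        y_hat = np.argmax(class_probs, axis=1)
        report.accuracy = float(accuracy_score(y_class, y_hat))
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_class, y_hat, labels=labels, average="macro", zero_division=0)
        report.precision, report.recall, report.f1 = float(prec), float(rec), float(f1)
        report.confusion = confusion_matrix(y_class, y_hat, labels=labels)
        for c, name in enumerate(CLASS_NAMES):
            binary = (np.asarray(y_class) == c).astype(int)
            if binary.min() == binary.max():  # class absent (or alone): undefined
                report.auc_per_class[name] = float("nan")
            else:
                report.auc_per_class[name] = float(
                    roc_auc_score(binary, class_probs[:, c]))

    if y_conc is not None and conc_pred is not None:
        y_conc = np.asarray(y_conc, dtype=float)
        conc_pred = np.asarray(conc_pred, dtype=float)
        err = np.abs(conc_pred - y_conc)
        report.mae = float(err.mean())
        report.r2 = float(pooled_r2(y_conc, conc_pred))
        for j, gas in enumerate(gas_names):
            report.mae_per_gas[gas] = float(err[:, j].mean())
            report.r2_per_gas[gas] = float(pooled_r2(y_conc[:, [j]], conc_pred[:, [j]]))
    return report


def evaluate(net, dataset, conc_scale: float = 1.0) -> MetricsReport:
    """Eval-mode metrics of a network on a :class:`LabeledDataset`.

    `conc_scale` rescales the regression outputs back to ppm when the
    network was trained on scaled targets.
    """
    if len(dataset) == 0:
        raise ValueError("empty test set")
    probs, conc = net.predict(dataset.X)
    return compute_metrics(
        dataset.y_class if probs is not None else None, probs,
        dataset.y_conc if conc is not None else None,
        None if conc is None else conc * conc_scale,
    )


def aggregate_reports(reports: list[MetricsReport]) -> dict[str, dict[str, float]]:
    """Mean and standard error (sd / sqrt(k)) of each scalar metric across folds."""
    out = {}
    k = len(reports)
    for key in reports[0].scalars():
        vals = np.array([r.scalars()[key] for r in reports], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            out[key] = {"mean": float("nan"), "stderr": float("nan")}
        else:
            sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
            out[key] = {"mean": float(vals.mean()),
                        "stderr": float(sd / np.sqrt(len(vals)))}
    return out
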