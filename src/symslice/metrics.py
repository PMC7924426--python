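"""Confusion-matrix evaluation metrics.

Multi-class performance is summarized by accuracy plus the macro means of
sensitivity, specificity, precision, F-measure, and G-mean, each computed
per class in one-vs-rest fashion from TP/TN/FP/FN and then averaged:

    accuracy    = trace / total              (micro)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F-measure   = 2 * precision * sensitivity / (precision + sensitivity)
    G-mean      = sqrt(sensitivity * specificity)

A class whose denominator vanishes (e.g. never predicted) contributes 0 to
the macro mean and is flagged in the report.  Note the macro F-measure is
the mean of per-class F values — generally *not* the F of the macro
precision/recall pair.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

METRIC_COLUMNS = ("Accuracy", "Sensitivity", "Specificity", "Precision", "F-Measure", "G-Mean")


class MetricsError(Exception):
    pass


@dataclass
class ConfusionMatrix:
    """K x K counts: rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise MetricsError(f"confusion matrix must be square, got {c.shape}")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.number):
            raise MetricsError("confusion matrix counts must be non-negative numbers")
        self.counts = c.astype(np.int64)

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int) -> "ConfusionMatrix":
        counts = np.zeros((n_classes, n_classes), dtype=np.int64)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[int(t), int(p)] += 1
        return cls(counts)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for class ``c`` against the rest."""
        total = int(self.counts.sum())
        tp = int(self.counts[c, c])
        fn = int(self.counts[c].sum()) - tp
        fp = int(self.counts[:, c].sum()) - tp
        tn = total - tp - fn - fp
        return tp, tn, fp, fn


@dataclass
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    g_mean: float
    per_class: dict[int, dict[str, float]] = field(default_factory=dict)
    flagged_classes: list[int] = field(default_factory=list)

    def as_row(self) -> dict[str, float]:
        return dict(
            zip(
                METRIC_COLUMNS,
                (
                    self.accuracy,
                    self.sensitivity,
                    self.specificity,
                    self.precision,
                    self.f_measure,
                    self.g_mean,
                ),
            )
        )

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = json.dumps(
            {
                **{k.lower().replace("-", "_"): v for k, v in self.as_row().items()},
                "per_class": self.per_class,
                "flagged_classes": self.flagged_classes,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_csv(self, path: str | os.PathLike) -> None:
        import pandas as pd

        pd.DataFrame([self.as_row()]).to_csv(path, index=False)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Macro-averaged one-vs-rest metrics (accuracy is micro: trace/total)."""
    total = int(cm.counts.sum())
    if total == 0:
        raise MetricsError("confusion matrix is empty")
    accuracy = float(np.trace(cm.counts)) / total

    per_class: dict[int, dict[str, float]] = {}
    flagged: list[int] = []
    sens_l, spec_l, prec_l, f_l, g_l = [], [], [], [], []
    for c in range(cm.n_classes):
        tp, tn, fp, fn = cm.one_vs_rest(c)
        sens, bad_s = _safe_div(tp, tp + fn)
        spec, bad_p = _safe_div(tn, tn + fp)
        prec, bad_pr = _safe_div(tp, tp + fp)
        f, bad_f = _safe_div(2 * prec * sens, prec + sens)
        g = float(np.sqrt(sens * spec))
        if bad_s or bad_p or bad_pr or bad_f:
            flagged.append(c)
            warnings.warn(
                f"class {c}: zero denominator in a metric; it contributes 0 to the macro mean",
                stacklevel=2,
            )
        per_class[c] = {
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "f_measure": f,
            "g_mean": g,
        }
        sens_l.append(sens)
        spec_l.append(spec)
        prec_l.append(prec)
        f_l.append(f)
        g_l.append(g)

    return MetricReport(
        accuracy=accuracy,
        sensitivity=float(np.mean(sens_l)),
        specificity=float(np.mean(spec_l)),
        precision=float(np.mean(prec_l)),
        f_measure=float(np.mean(f_l)),
        g_mean=float(np.mean(g_l)),
        per_class=per_class,
        flagged_classes=flagged,
    )
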