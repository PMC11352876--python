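"""Confusion-matrix construction and the nine-metric evaluation report.

All metrics are reported on a percent scale (including MCC and kappa,
whose raw [-1, 1] values are available via ``scale="raw"``) and any 0/0
ratio is defined as 0.  Rounding happens only at presentation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import SEIZURE
from .errors import ConfigurationError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "METRIC_ORDER",
    "confusion",
    "compute_metrics",
    "f1_from_pr",
    "fm_from_pr",
    "render_table",
]

#: Presentation row order of the report.
METRIC_ORDER = (
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "f1",
    "mcc",
    "kappa",
    "csi",
    "fm_index",
)


@dataclass
class ConfusionMatrix:
    """Binary confusion counts with seizure as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    kappa: float
    csi: float
    fm_index: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_ORDER}


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def confusion(
    y_true: Sequence, y_pred: Sequence, positive=SEIZURE
) -> ConfusionMatrix:
    """Tally binary confusion counts; ``positive`` marks the seizure class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise ConfigurationError("y_true and y_pred must be equal-length non-empty 1-D")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def compute_metrics(cm: ConfusionMatrix, scale: str = "percent") -> MetricsReport:
    """Derive the nine-metric report from a confusion matrix.

    ``scale="percent"`` (default) multiplies everything by 100 to match the
    usual presentation; ``scale="raw"`` leaves proportions in [0, 1] and
    MCC/kappa in [-1, 1].
    """
    if scale not in ("percent", "raw"):
        raise ConfigurationError(f"unknown scale {scale!r}")
    if cm.total < 1:
        raise ConfigurationError("confusion matrix must contain at least one count")
    tp, fp, tn, fn = float(cm.tp), float(cm.fp), float(cm.tn), float(cm.fn)
    total = tp + fp + tn + fn

    accuracy = _ratio(tp + tn, total)
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    precision = _ratio(tp, tp + fp)
    f1 = _ratio(2 * precision * sensitivity, precision + sensitivity)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den)
    p_o = accuracy
    p_e = _ratio((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn), total * total)
    kappa = _ratio(p_o - p_e, 1.0 - p_e)
    csi = _ratio(tp, tp + fp + fn)
    fm = math.sqrt(precision * sensitivity)

    factor = 100.0 if scale == "percent" else 1.0
    return MetricsReport(
        accuracy=accuracy * factor,
        sensitivity=sensitivity * factor,
        specificity=specificity * factor,
        precision=precision * factor,
        f1=f1 * factor,
        mcc=mcc * factor,
        kappa=kappa * factor,
        csi=csi * factor,
        fm_index=fm * factor,
    )


def f1_from_pr(precision_pct: float, sensitivity_pct: float) -> float:
    """Harmonic mean of precision and sensitivity, percent in / percent out.

    Defined as 0 when both inputs are 0.
    """
    _check_pct(precision_pct, sensitivity_pct)
    return _ratio(2.0 * precision_pct * sensitivity_pct, precision_pct + sensitivity_pct)


def fm_from_pr(precision_pct: float, sensitivity_pct: float) -> float:
    """Geometric mean (Fowlkes-Mallows index) of precision and sensitivity."""
    _check_pct(precision_pct, sensitivity_pct)
    return math.sqrt(precision_pct * sensitivity_pct)


def _check_pct(p: float, r: float) -> None:
    if not (0 <= p <= 100 and 0 <= r <= 100):
        raise ConfigurationError(f"percent inputs must lie in [0, 100], got ({p}, {r})")


def render_table(reports: dict[str, MetricsReport], decimals: int = 2) -> str:
    """Render one or more reports as a TSV table, metrics as rows in the
    standard presentation order and one column per report."""
    names = list(reports)
    lines = ["metric\t" + "\t".join(names)]
    for metric in METRIC_ORDER:
        row = [metric] + [f"{getattr(reports[n], metric):.{decimals}f}" for n in names]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
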