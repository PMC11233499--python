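"""Regression-to-risk-class decision layer and its metrics.

Numeric predictions (or measurements) are categorized against per-task
thresholds on the raw assay scale into low risk / inconclusive (medium) /
high risk. Predictions in the medium band are withheld from decision-making;
the reported metrics are the per-class opposite-extreme misclassification
error (predicted low but measured high, and vice versa), per-class precision
with any non-matching measured class counted as a false positive, the
inconclusive fraction, and the regression MAE.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .tasks import TaskSpec


class RiskClass(str, Enum):
    LOW = "low_risk"
    MEDIUM = "inconclusive_medium"
    HIGH = "high_risk"
    NOT_APPLICABLE = "not_applicable"


def categorize(value: float, spec: TaskSpec, scale: str = "model") -> RiskClass:
    """Assign a risk class to one value.

    ``scale='model'`` back-transforms to the raw assay scale first;
    ``scale='raw'`` applies thresholds directly. Tasks without thresholds
    return NOT_APPLICABLE. Boundary semantics follow the printed rules
    exactly (e.g. CL_int <= 100 is low risk, boundary inclusive).
    """
    if not spec.has_risk_rules:
        return RiskClass.NOT_APPLICABLE
    if scale == "model":
        raw = spec.from_model_scale(value)
    elif scale == "raw":
        raw = float(value)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if spec.low_risk_rule.satisfied(raw):
        return RiskClass.LOW
    if spec.high_risk_rule.satisfied(raw):
        return RiskClass.HIGH
    return RiskClass.MEDIUM


def categorize_many(values: Sequence[float], spec: TaskSpec, scale: str = "model") -> list[RiskClass]:
    return [categorize(v, spec, scale) for v in values]


@dataclass(frozen=True)
class RegressionReport:
    """Mean absolute error on model scale."""

    n: int
    mae: float

    def __post_init__(self) -> None:
        if self.mae < 0:
            raise ValueError("mae must be >= 0")


def mae(preds: Sequence[float], labels: Sequence[float]) -> RegressionReport:
    """Mean absolute error over paired predictions and labels."""
    p = np.asarray(preds, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("preds and labels must be paired")
    if p.size == 0:
        raise ValueError("mae of empty input")
    return RegressionReport(n=int(p.size), mae=float(np.abs(y - p).mean()))


@dataclass(frozen=True)
class ClassificationReport:
    """Three-class decision metrics (percentages in [0, 100]).

    ``error_low``: % of predicted-low compounds with a measured-high value
    (opposite extreme only); ``error_high`` symmetric. ``precision_*``: % of
    predicted-c compounds whose measured class is c (measured medium counts
    as a false positive). ``inconclusive_pct``: % of all predictions in the
    medium band. ``n_pred_low``/``n_pred_high`` flag empty denominators, for
    which errors/precision are reported as 0.
    """

    n: int
    error_low: float
    error_high: float
    precision_low: float
    precision_high: float
    inconclusive_pct: float
    n_pred_low: int
    n_pred_high: int
    confusion: dict

    def __post_init__(self) -> None:
        for v in (self.error_low, self.error_high, self.precision_low,
                  self.precision_high, self.inconclusive_pct):
            if not 0.0 <= v <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")


def classification_metrics(
    pred_classes: Sequence[RiskClass],
    measured_classes: Sequence[RiskClass],
    exclude_measured_medium: bool = False,
) -> ClassificationReport:
    """Compare predicted and measured risk classes for one task.

    With ``exclude_measured_medium`` the error/precision denominators drop
    compounds whose measured value falls in the medium band (they always
    stay out of the opposite-extreme error numerators).
    """
    if len(pred_classes) != len(measured_classes):
        raise ValueError("paired class lists required")
    for c in list(pred_classes) + list(measured_classes):
        if c is RiskClass.NOT_APPLICABLE:
            raise ValueError("classes from a task without thresholds")
    n = len(pred_classes)
    pairs = list(zip(pred_classes, measured_classes))

    conf: dict[str, int] = {}
    for p, m in pairs:
        key = f"pred_{p.name.lower()}|measured_{m.name.lower()}"
        conf[key] = conf.get(key, 0) + 1

    def rates(pred_c: RiskClass, opposite: RiskClass) -> tuple[float, float, int]:
        denom = [
            (p, m) for p, m in pairs
            if p is pred_c and not (exclude_measured_medium and m is RiskClass.MEDIUM)
        ]
        n_pred = len(denom)
        if n_pred == 0:
            return 0.0, 0.0, 0
        n_opp = sum(1 for _, m in denom if m is opposite)
        n_tp = sum(1 for _, m in denom if m is pred_c)
        return 100.0 * n_opp / n_pred, 100.0 * n_tp / n_pred, n_pred

    error_low, precision_low, n_pred_low = rates(RiskClass.LOW, RiskClass.HIGH)
    error_high, precision_high, n_pred_high = rates(RiskClass.HIGH, RiskClass.LOW)
    n_medium = sum(1 for p, _ in pairs if p is RiskClass.MEDIUM)
    return ClassificationReport(
        n=n,
        error_low=error_low,
        error_high=error_high,
        precision_low=precision_low,
        precision_high=precision_high,
        inconclusive_pct=100.0 * n_medium / n if n else 0.0,
        n_pred_low=n_pred_low,
        n_pred_high=n_pred_high,
        confusion=conf,
    )
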