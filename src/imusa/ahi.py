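"""AHI estimation from event indices and severity classification.

The respiratory event index (REI) is a device-specific linear combination of
the four hourly event indices, clipped at zero. Severity classes use
lower-closed intervals on either the AHI grid (5/15/30) or the device's REI
cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .events import EventIndices
from .io_formats import DeviceModel

SEVERITY_ORDER = ("no_sa", "mild", "moderate", "severe")
AHI_CUTOFFS = (5.0, 15.0, 30.0)


@dataclass(frozen=True)
class ReiEstimate:
    rei: float
    device_label: str
    raw_linear_value: float


def estimate_rei(indices: EventIndices, model: DeviceModel) -> ReiEstimate:
    """Linear REI prediction; negative raw values are clipped to 0."""
    raw = (
        model.intercept
        + model.coef_raei_acc * indices.raei_acc
        + model.coef_rfei_acc * indices.rfei_acc
        + model.coef_raei_gyro * indices.raei_gyro
        + model.coef_rfei_gyro * indices.rfei_gyro
    )
    return ReiEstimate(rei=max(0.0, raw), device_label=model.device_label, raw_linear_value=raw)


def _classify(value: float, cutoffs: Sequence[float]) -> str:
    c_mild, c_moderate, c_severe = cutoffs
    if value >= c_severe:
        return "severe"
    if value >= c_moderate:
        return "moderate"
    if value >= c_mild:
        return "mild"
    return "no_sa"


def classify_severity_from_ahi(ahi: float) -> str:
    """Severity on the AHI grid: [0,5) / [5,15) / [15,30) / [30, inf)."""
    if ahi < 0:
        raise ValueError("AHI must be non-negative")
    return _classify(ahi, AHI_CUTOFFS)


def classify_severity_from_rei(rei: float, model: DeviceModel) -> str:
    """Severity using the device's REI cutoffs (lower-closed intervals)."""
    return _classify(max(0.0, rei), model.severity_cutoffs)


def binary_screen(rei: float, threshold: float) -> bool:
    """Positive screen when rei >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return rei >= threshold


def fit_device_model(
    index_rows: Sequence[EventIndices | Sequence[float]],
    ahi_values: Sequence[float],
    device_label: str = "generic",
    severity_cutoffs: tuple[float, float, float] = (5.0, 15.0, 30.0),
) -> DeviceModel:
    """Ordinary least squares of AHI on (RAEI_acc, RFEI_acc, RAEI_gyro, RFEI_gyro).

    Provided so users with labelled recordings can derive their own model;
    plain OLS, no regularization.
    """
    rows = []
    for r in index_rows:
        if isinstance(r, EventIndices):
            rows.append([r.raei_acc, r.rfei_acc, r.raei_gyro, r.rfei_gyro])
        else:
            rows.append(list(r))
    X = np.asarray(rows, dtype=float)
    y = np.asarray(ahi_values, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError("need 4 predictors per observation")
    if X.shape[0] != len(y):
        raise ValueError("predictor and response lengths differ")
    if X.shape[0] < 5:
        raise ValueError("need at least 5 observations to fit 5 parameters")
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return DeviceModel(
        device_label=device_label,
        intercept=float(beta[0]),
        coef_raei_acc=float(beta[1]),
        coef_rfei_acc=float(beta[2]),
        coef_raei_gyro=float(beta[3]),
        coef_rfei_gyro=float(beta[4]),
        severity_cutoffs=severity_cutoffs,
    )
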