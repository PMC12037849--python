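"""Text-based I/O for IMU recordings, event annotations, and device models.

Recordings are CSV files with a ``#``-prefixed YAML header describing the
device, sampling rate, units, and start offset.  All internal values are in
mG (acceleration) and dps (gyroscope); unit conversion happens only at this
boundary.  Missing samples are kept on the uniform time base and flagged in
``gap_mask`` rather than dropped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

DEVICE_LABELS = ("amue_link", "xperia", "iphone", "generic")

EVENT_TYPES = (
    "obstructive_apnea",
    "central_apnea",
    "mixed_apnea",
    "hypopnea",
    "respiratory_event",
)

RECORDING_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]

#: Conversion factors into internal units (mG for acceleration, dps for gyro).
_ACC_UNIT_FACTORS = {"mG": 1.0, "mg": 1.0, "G": 1000.0, "g": 1000.0}
_GYRO_UNIT_FACTORS = {"dps": 1.0, "rps": 180.0 / np.pi}


class FormatError(ValueError):
    """Raised when a file does not match the expected on-disk schema."""


class ValidationError(ValueError):
    """Raised when parsed data violates a structural invariant."""


@dataclass
class ImuRecording:
    """Synchronized tri-axial acceleration + gyroscope time series.

    Parameters
    ----------
    device_label:
        One of :data:`DEVICE_LABELS`.
    sampling_rate_hz:
        Uniform sampling rate shared by all six channels.
    acceleration, gyroscope:
        Arrays of shape ``(3, N)`` in mG and dps respectively.
    start_offset_s:
        Offset of sample 0 relative to an external clock.
    gap_mask:
        Boolean array of length N; True marks missing/invalid samples.
    """

    device_label: str
    sampling_rate_hz: float
    acceleration: np.ndarray
    gyroscope: np.ndarray
    start_offset_s: float = 0.0
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.device_label not in DEVICE_LABELS:
            raise ValidationError(
                f"unknown device label {self.device_label!r}; expected one of {DEVICE_LABELS}"
            )
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")
        self.acceleration = np.asarray(self.acceleration, dtype=float)
        self.gyroscope = np.asarray(self.gyroscope, dtype=float)
        if self.acceleration.shape != self.gyroscope.shape or self.acceleration.ndim != 2:
            raise ValidationError("acceleration and gyroscope must both be (3, N)")
        if self.acceleration.shape[0] != 3:
            raise ValidationError("expected 3 axes per sensor")
        n = self.acceleration.shape[1]
        if self.gap_mask is None:
            self.gap_mask = np.zeros(n, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.shape != (n,):
                raise ValidationError("gap_mask length must match sample count")
        ok = ~self.gap_mask
        if not (
            np.isfinite(self.acceleration[:, ok]).all()
            and np.isfinite(self.gyroscope[:, ok]).all()
        ):
            raise ValidationError("non-gap samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.acceleration.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def duration_hours(self) -> float:
        return self.duration_s / 3600.0

    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass(frozen=True)
class Annotation:
    """A single scored event on the half-open interval [onset, onset+duration)."""

    onset_s: float
    duration_s: float
    type: str

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValidationError("event onset must be >= 0")
        if not self.duration_s > 0:
            raise ValidationError("event duration must be positive")
        if self.type not in EVENT_TYPES:
            raise ValidationError(
                f"unknown event type {self.type!r}; accepted types: {', '.join(EVENT_TYPES)}"
            )

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class AnnotationSet:
    """Time-sorted collection of scored respiratory events."""

    events: list[Annotation]
    total_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.onset_s, e.end_s))
        if self.events:
            last_end = max(e.end_s for e in self.events)
            if self.total_time_s <= 0.0:
                self.total_time_s = last_end
            elif last_end > self.total_time_s + 1e-9:
                raise ValidationError("event extends beyond total_time_s")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass(frozen=True)
class DeviceModel:
    """Regression coefficients and severity cutoffs for one device.

    ``estimate = intercept + coef_raei_acc*RAEI_acc + coef_rfei_acc*RFEI_acc
    + coef_raei_gyro*RAEI_gyro + coef_rfei_gyro*RFEI_gyro``; cutoffs are the
    lower-closed class boundaries (mild, moderate, severe) on the REI scale.
    """

    device_label: str
    intercept: float
    coef_raei_acc: float
    coef_rfei_acc: float
    coef_raei_gyro: float
    coef_rfei_gyro: float
    severity_cutoffs: tuple[float, float, float] = (5.0, 15.0, 30.0)

    def __post_init__(self) -> None:
        c_mild, c_moderate, c_severe = self.severity_cutoffs
        if not (c_mild < c_moderate < c_severe):
            raise ValidationError("severity cutoffs must be strictly increasing")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array(
            [
                self.coef_raei_acc,
                self.coef_rfei_acc,
                self.coef_raei_gyro,
                self.coef_rfei_gyro,
            ]
        )


DEFAULT_DEVICE_MODELS: dict[str, DeviceModel] = {
    "amue_link": DeviceModel(
        "amue_link", 1.71, 0.20, 0.82, -0.44, -2.60, severity_cutoffs=(5.0, 17.0, 30.0)
    ),
    "xperia": DeviceModel(
        "xperia", 1.43, 0.17, 0.84, 0.21, -5.64, severity_cutoffs=(5.0, 15.0, 30.0)
    ),
    "iphone": DeviceModel(
        "iphone", 0.34, 0.95, 0.71, -0.62, 1.36, severity_cutoffs=(5.0, 13.0, 36.0)
    ),
}


# ---------------------------------------------------------------------------
# recordings


def _parse_header(path: Path) -> tuple[dict, int]:
    """Parse the leading '#' comment block as YAML; return (header, n_lines)."""
    lines = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#"):
                lines.append(raw.lstrip("#").rstrip("\n"))
            else:
                break
    header = yaml.safe_load("\n".join(lines)) if lines else None
    return (header or {}), len(lines)


def read_recording(path: str | Path, schema: dict | None = None) -> ImuRecording:
    """Read a CSV recording with a YAML header into an :class:`ImuRecording`.

    ``schema`` entries override header fields (e.g. to force a sampling rate
    for a headerless export). Unreadable samples become gap-mask entries.
    """
    path = Path(path)
    header, n_header = _parse_header(path)
    if schema:
        header = {**header, **schema}

    required = ("sampling_rate_hz", "acc_units", "gyro_units")
    missing = [k for k in required if k not in header]
    if missing:
        raise FormatError(f"{path}: missing header fields: {', '.join(missing)}")

    df = pd.read_csv(path, skiprows=n_header)
    if list(df.columns) != RECORDING_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {RECORDING_COLUMNS}, found {list(df.columns)}"
        )

    acc_units = str(header["acc_units"])
    gyro_units = str(header["gyro_units"])
    if acc_units not in _ACC_UNIT_FACTORS:
        raise FormatError(f"unknown acceleration units {acc_units!r}")
    if gyro_units not in _GYRO_UNIT_FACTORS:
        raise FormatError(f"unknown gyroscope units {gyro_units!r}")

    acc = df[["ax", "ay", "az"]].to_numpy(dtype=float).T * _ACC_UNIT_FACTORS[acc_units]
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float).T * _GYRO_UNIT_FACTORS[gyro_units]

    gap = ~(np.isfinite(acc).all(axis=0) & np.isfinite(gyro).all(axis=0))
    return ImuRecording(
        device_label=str(header.get("device", "generic")),
        sampling_rate_hz=float(header["sampling_rate_hz"]),
        acceleration=acc,
        gyroscope=gyro,
        start_offset_s=float(header.get("start_offset_s", 0.0)),
        gap_mask=gap,
    )


def write_recording(recording: ImuRecording, path: str | Path, precision: int = 6) -> None:
    """Write a recording to CSV with its YAML header; gaps become NaN rows."""
    path = Path(path)
    acc = recording.acceleration.copy()
    gyro = recording.gyroscope.copy()
    acc[:, recording.gap_mask] = np.nan
    gyro[:, recording.gap_mask] = np.nan
    df = pd.DataFrame(
        {
            "t": recording.times(),
            "ax": acc[0],
            "ay": acc[1],
            "az": acc[2],
            "gx": gyro[0],
            "gy": gyro[1],
            "gz": gyro[2],
        }
    )
    header = {
        "device": recording.device_label,
        "sampling_rate_hz": recording.sampling_rate_hz,
        "acc_units": "mG",
        "gyro_units": "dps",
        "start_offset_s": recording.start_offset_s,
    }
    buf = io.StringIO()
    for line in yaml.safe_dump(header, sort_keys=False).strip().splitlines():
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=False, float_format=f"%.{precision}g")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read an event CSV (onset_s, duration_s, type) into an AnnotationSet."""
    path = Path(path)
    header, n_header = _parse_header(path)
    df = pd.read_csv(path, skiprows=n_header)
    for col in ("onset_s", "duration_s", "type"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    events = [
        Annotation(float(r.onset_s), float(r.duration_s), str(r.type))
        for r in df.itertuples()
    ]
    return AnnotationSet(events, total_time_s=float(header.get("total_time_s", 0.0)))


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# total_time_s: {annotations.total_time_s}\n")
    pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in annotations],
            "duration_s": [e.duration_s for e in annotations],
            "type": [e.type for e in annotations],
        }
    ).to_csv(buf, index=False)
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# device models


def load_device_model(
    name_or_path: str | Path, overrides: dict | None = None
) -> DeviceModel:
    """Load a device model by built-in name or from a YAML config file.

    YAML schema::

        device: xperia
        intercept: 1.43
        coefficients: {raei_acc: 0.17, rfei_acc: 0.84, raei_gyro: 0.21, rfei_gyro: -5.64}
        cutoffs: {mild: 5, moderate: 15, severe: 30}
    """
    name = str(name_or_path)
    if name in DEFAULT_DEVICE_MODELS:
        model = DEFAULT_DEVICE_MODELS[name]
        if overrides:
            model = replace(model, **overrides)
        return model

    path = Path(name_or_path)
    if not path.exists():
        raise ValidationError(
            f"unknown device {name!r} and no such config file; "
            f"built-in devices: {', '.join(DEFAULT_DEVICE_MODELS)}"
        )
    cfg = yaml.safe_load(path.read_text()) or {}
    if overrides:
        cfg = {**cfg, **overrides}
    device = cfg.get("device", "generic")
    base = DEFAULT_DEVICE_MODELS.get(device)
    coefs = cfg.get("coefficients", {}) or {}
    cuts = cfg.get("cutoffs", {}) or {}

    def pick(key: str, sub: dict, base_value: float) -> float:
        return float(sub[key]) if key in sub else base_value

    if base is None:
        base = DeviceModel("generic", 0.0, 0.0, 0.0, 0.0, 0.0)
    return DeviceModel(
        device_label=device,
        intercept=float(cfg.get("intercept", base.intercept)),
        coef_raei_acc=pick("raei_acc", coefs, base.coef_raei_acc),
        coef_rfei_acc=pick("rfei_acc", coefs, base.coef_rfei_acc),
        coef_raei_gyro=pick("raei_gyro", coefs, base.coef_raei_gyro),
        coef_rfei_gyro=pick("rfei_gyro", coefs, base.coef_rfei_gyro),
        severity_cutoffs=(
            pick("mild", cuts, base.severity_cutoffs[0]),
            pick("moderate", cuts, base.severity_cutoffs[1]),
            pick("severe", cuts, base.severity_cutoffs[2]),
        ),
    )


def save_device_model(model: DeviceModel, path: str | Path) -> None:
    cfg = {
        "device": model.device_label,
        "intercept": float(model.intercept),
        "coefficients": {
            "raei_acc": float(model.coef_raei_acc),
            "rfei_acc": float(model.coef_rfei_acc),
            "raei_gyro": float(model.coef_raei_gyro),
            "rfei_gyro": float(model.coef_rfei_gyro),
        },
        "cutoffs": {
            "mild": float(model.severity_cutoffs[0]),
            "moderate": float(model.severity_cutoffs[1]),
            "severe": float(model.severity_cutoffs[2]),
        },
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
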