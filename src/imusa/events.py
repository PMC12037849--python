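"""Respiratory-event detection from amplitude and frequency series.

An amplitude event is a 10–90 s run where the fast (3-s) 95th-percentile
envelope of RA falls more than 30% below the slow (30-s) envelope. A
frequency event is a 10–90 s run where RF falls more than 30% below its own
30-s upper envelope, suppressed wherever the amplitude criterion already
holds (no double counting). Both detectors run independently per sensor
channel; hourly counts give the RAEI / RFEI indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import Annotation, AnnotationSet, ImuRecording
from .respiration import (
    FilterSpec,
    RespiratoryAmplitudeSeries,
    RespiratoryFrequencySeries,
    bandpass_axis,
    bridge_gaps,
    build_respiratory_waveform,
    respiratory_amplitude,
    respiratory_frequency,
    select_dominant_axes,
)

CHANNELS = ("acceleration", "gyroscope")
SOURCES = ("amplitude", "frequency")


@dataclass(frozen=True)
class DetectionConfig:
    """Named constants of the event criteria (single source of truth)."""

    drop_fraction: float = 0.30
    min_duration_s: float = 10.0
    max_duration_s: float = 90.0
    fast_window_s: float = 3.0
    slow_window_s: float = 30.0
    percentile: float = 95.0
    min_recording_s: float = 300.0


@dataclass(frozen=True)
class RespiratoryEvent:
    onset_s: float
    duration_s: float
    source: str  # amplitude | frequency
    channel: str  # acceleration | gyroscope

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class EventIndices:
    """Hourly event rates per channel x source plus the monitoring time."""

    raei_acc: float
    rfei_acc: float
    raei_gyro: float
    rfei_gyro: float
    monitoring_hours: float

    def as_dict(self) -> dict:
        return {
            "raei_acc": self.raei_acc,
            "rfei_acc": self.rfei_acc,
            "raei_gyro": self.raei_gyro,
            "rfei_gyro": self.rfei_gyro,
            "monitoring_hours": self.monitoring_hours,
        }


@dataclass
class DetectionResult:
    events: dict[tuple[str, str], list[RespiratoryEvent]]
    indices: EventIndices

    def all_events(self) -> list[RespiratoryEvent]:
        out: list[RespiratoryEvent] = []
        for key in sorted(self.events):
            out.extend(self.events[key])
        return sorted(out, key=lambda e: e.onset_s)


def moving_percentile(
    series: np.ndarray, window_s: float, rate_hz: float, percentile: float = 95.0
) -> np.ndarray:
    """Centered moving percentile, truncated at the boundaries.

    The window is forced to an odd sample count so it is symmetric; edge
    windows shrink rather than pad.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    if window_s * rate_hz < 2:
        raise ValueError("window must span at least 2 samples")
    x = np.asarray(series, dtype=float)
    w = int(round(window_s * rate_hz))
    if w % 2 == 0:
        w += 1
    return (
        pd.Series(x)
        .rolling(window=w, center=True, min_periods=1)
        .quantile(percentile / 100.0, interpolation="linear")
        .to_numpy()
    )


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open index pairs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(len(m))
    return list(zip(starts, stops))


def _runs_to_events(
    mask: np.ndarray,
    rate_hz: float,
    source: str,
    channel: str,
    config: DetectionConfig,
) -> list[RespiratoryEvent]:
    events = []
    for start, stop in _mask_runs(mask):
        duration = (stop - start) / rate_hz
        # runs beyond the cap are dropped outright (signal-loss protection)
        if config.min_duration_s <= duration <= config.max_duration_s:
            events.append(RespiratoryEvent(start / rate_hz, duration, source, channel))
    return events


def amplitude_events(
    ra: RespiratoryAmplitudeSeries, config: DetectionConfig = DetectionConfig()
) -> tuple[list[RespiratoryEvent], np.ndarray]:
    """Detect amplitude events; also return the raw condition mask.

    The mask (fast envelope < (1 - drop) x slow envelope) is returned for
    every sample regardless of run duration, because it is what suppresses
    frequency-based detection downstream.
    """
    fast = moving_percentile(ra.values, config.fast_window_s, ra.sampling_rate_hz, config.percentile)
    slow = moving_percentile(ra.values, config.slow_window_s, ra.sampling_rate_hz, config.percentile)
    mask = fast < (1.0 - config.drop_fraction) * slow
    events = _runs_to_events(mask, ra.sampling_rate_hz, "amplitude", ra.channel, config)
    return events, mask


def frequency_events(
    rf: RespiratoryFrequencySeries,
    suppression: np.ndarray,
    channel: str = "acceleration",
    config: DetectionConfig = DetectionConfig(),
) -> list[RespiratoryEvent]:
    """Detect frequency events outside amplitude-suppressed spans."""
    supp = np.asarray(suppression, dtype=bool)
    if supp.shape != rf.values.shape:
        raise ValueError("suppression mask must share the RF time base")
    upper = moving_percentile(
        rf.values, config.slow_window_s, rf.sampling_rate_hz, config.percentile
    )
    mask = (rf.values < (1.0 - config.drop_fraction) * upper) & ~supp
    return _runs_to_events(mask, rf.sampling_rate_hz, "frequency", channel, config)


def _event_in_spans(event: RespiratoryEvent, spans: list[tuple[float, float]]) -> bool:
    return any(event.onset_s >= lo and event.end_s <= hi for lo, hi in spans)


def detect_all(
    recording: ImuRecording,
    config: DetectionConfig = DetectionConfig(),
    filter_spec: FilterSpec | None = None,
) -> DetectionResult:
    """Run the full detection chain on both sensor channels.

    Gap samples are linearly bridged before filtering; events lying entirely
    inside a bridged span are discarded. Monitoring time is the recording
    duration.
    """
    if recording.duration_s < config.min_recording_s:
        raise ValueError(
            f"recording of {recording.duration_s:.0f}s is too short; "
            f"need >= {config.min_recording_s:.0f}s to form stable envelopes"
        )
    spec = filter_spec or FilterSpec(sampling_rate_hz=recording.sampling_rate_hz)
    bridged_spans = [
        (start / recording.sampling_rate_hz, stop / recording.sampling_rate_hz)
        for start, stop in _mask_runs(recording.gap_mask)
    ]

    events: dict[tuple[str, str], list[RespiratoryEvent]] = {}
    for channel, raw in (
        ("acceleration", recording.acceleration),
        ("gyroscope", recording.gyroscope),
    ):
        filtered = np.stack(
            [bandpass_axis(bridge_gaps(raw[i], recording.gap_mask), spec) for i in range(3)]
        )
        ra = respiratory_amplitude(
            filtered[0], filtered[1], filtered[2], recording.sampling_rate_hz, channel
        )
        amp_events, supp = amplitude_events(ra, config)

        choices = select_dominant_axes(filtered, recording.sampling_rate_hz)
        waveform = build_respiratory_waveform(filtered, choices, spec)
        rf = respiratory_frequency(waveform)
        freq_events = frequency_events(rf, supp, channel, config)

        events[(channel, "amplitude")] = [
            e for e in amp_events if not _event_in_spans(e, bridged_spans)
        ]
        events[(channel, "frequency")] = [
            e for e in freq_events if not _event_in_spans(e, bridged_spans)
        ]

    hours = recording.duration_hours
    indices = EventIndices(
        raei_acc=len(events[("acceleration", "amplitude")]) / hours,
        rfei_acc=len(events[("acceleration", "frequency")]) / hours,
        raei_gyro=len(events[("gyroscope", "amplitude")]) / hours,
        rfei_gyro=len(events[("gyroscope", "frequency")]) / hours,
        monitoring_hours=hours,
    )
    return DetectionResult(events, indices)


def events_to_annotations(
    events: list[RespiratoryEvent], total_time_s: float
) -> AnnotationSet:
    """Export detected events using the annotation schema (type = respiratory_event)."""
    return AnnotationSet(
        [Annotation(e.onset_s, e.duration_s, "respiratory_event") for e in events],
        total_time_s=total_time_s,
    )


def events_to_frame(events: list[RespiratoryEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in events],
            "duration_s": [e.duration_s for e in events],
            "type": ["respiratory_event"] * len(events),
            "source": [e.source for e in events],
            "channel": [e.channel for e in events],
        }
    )


def events_from_frame(df: pd.DataFrame) -> list[RespiratoryEvent]:
    return [
        RespiratoryEvent(
            float(r.onset_s),
            float(r.duration_s),
            str(getattr(r, "source", "amplitude")),
            str(getattr(r, "channel", "acceleration")),
        )
        for r in df.itertuples()
    ]
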