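"""Synthetic overnight IMU recordings with known ground truth.

The respiratory carrier is a quasi-sinusoid (~14 cycles/min with lognormal
per-cycle jitter and slow amplitude drift) projected onto a scheduled body
axis; scheduled apnea/hypopnea episodes scale its amplitude and/or slow its
frequency; out-of-band contaminants (pulse ~1 Hz, movement bursts 2-4 Hz,
cardiac vibration >= 8 Hz, white noise) are added per channel. All
randomness flows from a single seed through spawned child generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .concordance import _overlap_labels
from .io_formats import Annotation, AnnotationSet, ImuRecording

#: Simulated event flavour -> annotation type.
_EVENT_TYPE_MAP = {
    "apnea": "central_apnea",
    "hypopnea": "hypopnea",
    "obstructive_freq": "obstructive_apnea",
}


@dataclass(frozen=True)
class EventSpec:
    """One scheduled breathing disturbance.

    ``apnea`` requires depth >= 0.9 (>90% amplitude reduction), ``hypopnea``
    0.3 < depth < 0.9, and ``obstructive_freq`` preserves amplitude
    (depth == 0) while reducing frequency only.
    """

    onset_s: float
    duration_s: float
    depth_fraction: float
    type: str = "apnea"
    freq_drop_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s < 10.0:
            raise ValueError("scheduled events must last at least 10 s")
        if self.type not in _EVENT_TYPE_MAP:
            raise ValueError(f"unknown event type {self.type!r}")
        if not 0.0 <= self.depth_fraction <= 1.0:
            raise ValueError("depth_fraction must lie in [0, 1]")
        if not 0.0 <= self.freq_drop_fraction < 1.0:
            raise ValueError("freq_drop_fraction must lie in [0, 1)")
        if self.type == "apnea" and self.depth_fraction < 0.9:
            raise ValueError("apnea events need depth_fraction >= 0.9")
        if self.type == "hypopnea" and not 0.3 < self.depth_fraction < 0.9:
            raise ValueError("hypopnea events need depth_fraction in (0.3, 0.9)")
        if self.type == "obstructive_freq":
            if self.depth_fraction != 0.0 or self.freq_drop_fraction <= 0.0:
                raise ValueError(
                    "obstructive_freq events preserve amplitude (depth 0) and "
                    "must reduce frequency"
                )

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class NoiseSpec:
    pulse_band_amp: float = 2.0
    movement_band_amp: float = 5.0
    hf_band_amp: float = 1.0
    white_sd: float = 1.0


@dataclass
class ScenarioSpec:
    duration_s: float
    sampling_rate_hz: float = 32.0
    breath_rate_cpm: float = 14.0
    breath_amplitude_mg: float = 20.0
    breath_amplitude_dps: float = 20.0
    respiratory_axis_schedule: list[tuple[float, tuple[float, float, float]]] = field(
        default_factory=lambda: [(0.0, (0.0, 0.0, 1.0))]
    )
    event_schedule: list[EventSpec] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    cycle_jitter_cv: float = 0.05
    amplitude_drift_fraction: float = 0.2
    amplitude_drift_period_s: float = 300.0
    gravity_mg: float = 1000.0
    gravity_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    posture_transition_s: float = 3.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        events = sorted(self.event_schedule, key=lambda e: e.onset_s)
        for a, b in zip(events, events[1:]):
            if b.onset_s < a.end_s:
                raise ValueError(f"overlapping events at {a.onset_s}s and {b.onset_s}s")
        for e in events:
            if e.end_s > self.duration_s:
                raise ValueError("event extends beyond the recording")
        self.event_schedule = events
        sched = sorted(self.respiratory_axis_schedule, key=lambda s: s[0])
        if not sched or sched[0][0] > 0.0:
            sched.insert(0, (0.0, (0.0, 0.0, 1.0)))
        norm_sched = []
        for start, vec in sched:
            v = np.asarray(vec, dtype=float)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError("axis vectors must be non-zero")
            norm_sched.append((float(start), tuple(v / n)))
        self.respiratory_axis_schedule = norm_sched


@dataclass
class GroundTruth:
    events: AnnotationSet
    breath_nadir_times_s: np.ndarray
    posture_change_times_s: list[float]
    ref_positive: np.ndarray  # per breath


def _cycle_frequency(spec: ScenarioSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-sample instantaneous frequency with lognormal per-cycle jitter."""
    base_period = 60.0 / spec.breath_rate_cpm
    cv = spec.cycle_jitter_cv
    sigma = np.sqrt(np.log1p(cv**2))
    mu = -0.5 * sigma**2
    n_cycles = int(np.ceil(spec.duration_s / base_period * 1.5)) + 8
    periods = base_period * rng.lognormal(mu, sigma, size=n_cycles)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(n) / spec.sampling_rate_hz
    cycle_of = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n_cycles - 1)
    return 1.0 / periods[cycle_of]


def _ramped_factor(
    t: np.ndarray, events: Sequence[EventSpec], value, ramp_s: float = 1.0
) -> np.ndarray:
    """Multiplicative factor that dips to `value(e)` inside each event with linear ramps."""
    factor = np.ones_like(t)
    for e in events:
        v = value(e)
        if v == 1.0:
            continue
        rise = np.clip((t - e.onset_s) / ramp_s, 0.0, 1.0)
        fall = np.clip((e.end_s - t) / ramp_s, 0.0, 1.0)
        inside = np.minimum(rise, fall)
        factor *= 1.0 - (1.0 - v) * inside
    return factor


def _axis_direction(spec: ScenarioSpec, t: np.ndarray) -> np.ndarray:
    """(3, N) unit-ish direction with smooth transitions at posture changes."""
    sched = spec.respiratory_axis_schedule
    u = np.tile(np.asarray(sched[0][1], dtype=float)[:, None], (1, len(t)))
    for (start, vec), (_, prev_vec) in zip(sched[1:], sched[:-1]):
        w = np.clip((t - start) / max(spec.posture_transition_s, 1e-9), 0.0, 1.0)
        blend = np.outer(np.asarray(prev_vec), 1.0 - w) + np.outer(np.asarray(vec), w)
        after = t >= start
        u[:, after] = blend[:, after]
    norms = np.linalg.norm(u, axis=0)
    norms[norms == 0] = 1.0
    return u / norms


def _channel_noise(
    spec: ScenarioSpec, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(3, N) out-of-band contaminant mix for one sensor."""
    ns = spec.noise
    n = len(t)
    out = np.zeros((3, n))
    for ax in range(3):
        sig = np.zeros(n)
        if ns.pulse_band_amp > 0:
            f = rng.uniform(0.9, 1.5)
            sig += ns.pulse_band_amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        if ns.hf_band_amp > 0:
            f = rng.uniform(8.0, min(12.0, 0.45 * spec.sampling_rate_hz))
            sig += ns.hf_band_amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        if ns.movement_band_amp > 0:
            n_bursts = rng.poisson(spec.duration_s / 900.0)
            for _ in range(n_bursts):
                start = rng.uniform(0, spec.duration_s)
                dur = rng.uniform(2.0, 5.0)
                f = rng.uniform(2.0, 4.0)
                env = np.clip(1 - np.abs((t - start - dur / 2) / (dur / 2)), 0, 1)
                sig += ns.movement_band_amp * rng.uniform(0.5, 1.5) * env * np.sin(
                    2 * np.pi * f * t
                )
        if ns.white_sd > 0:
            sig += rng.normal(0.0, ns.white_sd, size=n)
        out[ax] = sig
    return out


def simulate(spec: ScenarioSpec) -> tuple[ImuRecording, GroundTruth]:
    """Generate a recording and its ground truth, deterministically per seed."""
    fs = spec.sampling_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(spec.seed)
    rng_carrier, rng_acc, rng_gyro = rng.spawn(3)

    freq = _cycle_frequency(spec, n, rng_carrier)
    freq *= _ramped_factor(t, spec.event_schedule, lambda e: 1.0 - e.freq_drop_fraction)
    phase = 2.0 * np.pi * np.cumsum(freq) / fs
    carrier = np.sin(phase)

    drift = 1.0 + spec.amplitude_drift_fraction * np.sin(
        2 * np.pi * t / spec.amplitude_drift_period_s
        + rng_carrier.uniform(0, 2 * np.pi)
    )
    envelope = drift * _ramped_factor(
        t, spec.event_schedule, lambda e: 1.0 - e.depth_fraction
    )

    u = _axis_direction(spec, t)
    resp = envelope * carrier
    # gravity stays on a fixed body axis: the belt holds the device in place,
    # while posture shifts re-orient the respiratory movement vector
    g_vec = np.asarray(spec.gravity_axis, dtype=float)
    g_vec = g_vec / (np.linalg.norm(g_vec) or 1.0)
    acc = spec.breath_amplitude_mg * resp * u + spec.gravity_mg * g_vec[:, None]
    gyro = spec.breath_amplitude_dps * resp * u
    acc += _channel_noise(spec, t, rng_acc)
    gyro += _channel_noise(spec, t, rng_gyro)

    recording = ImuRecording(
        device_label="generic",
        sampling_rate_hz=fs,
        acceleration=acc,
        gyroscope=gyro,
    )

    # carrier minima sit at phase = 3*pi/2 (mod 2*pi); phase is monotone
    targets = np.arange(1.5 * np.pi, phase[-1], 2.0 * np.pi)
    nadirs = np.interp(targets, phase, t)

    annotations = AnnotationSet(
        [
            Annotation(e.onset_s, e.duration_s, _EVENT_TYPE_MAP[e.type])
            for e in spec.event_schedule
        ],
        total_time_s=spec.duration_s,
    )
    intervals = np.column_stack([nadirs[:-1], nadirs[1:]])
    ref_positive = _overlap_labels(
        intervals, [(e.onset_s, e.end_s) for e in spec.event_schedule]
    )
    truth = GroundTruth(
        events=annotations,
        breath_nadir_times_s=nadirs,
        posture_change_times_s=[s for s, _ in spec.respiratory_axis_schedule[1:]],
        ref_positive=ref_positive,
    )
    return recording, truth


# ---------------------------------------------------------------------------
# presets


def _mixed_schedule(
    duration_s: float, events_per_hour: float, start_s: float = 90.0
) -> list[EventSpec]:
    """Evenly spaced events cycling apnea / hypopnea / frequency-only flavours."""
    interval = 3600.0 / events_per_hour
    flavours = [
        dict(duration_s=20.0, depth_fraction=0.95, type="apnea"),
        dict(duration_s=18.0, depth_fraction=0.60, type="hypopnea", freq_drop_fraction=0.3),
        dict(duration_s=22.0, depth_fraction=0.0, type="obstructive_freq", freq_drop_fraction=0.5),
        dict(duration_s=15.0, depth_fraction=0.92, type="apnea"),
    ]
    events = []
    onset = start_s
    k = 0
    while onset + 30.0 <= duration_s:
        f = flavours[k % len(flavours)]
        if onset + f["duration_s"] + 10.0 > duration_s:
            break
        events.append(EventSpec(onset_s=onset, **f))
        onset += interval
        k += 1
    return events


_POSTURE_VECTORS = [
    (0.0, 0.0, 1.0),
    (0.6, 0.0, 0.8),
    (0.0, 0.7, 0.714),
    (0.5, 0.5, 0.707),
]


def scenario_presets(
    duration_s: float = 3600.0, sampling_rate_hz: float = 32.0, seed: int = 0
) -> dict[str, ScenarioSpec]:
    """Named scenarios covering the main operating regimes."""

    def base(**kw) -> ScenarioSpec:
        return ScenarioSpec(
            duration_s=duration_s, sampling_rate_hz=sampling_rate_hz, seed=seed, **kw
        )

    rotations = [
        (k * 900.0, _POSTURE_VECTORS[k % len(_POSTURE_VECTORS)])
        for k in range(int(duration_s // 900.0) + 1)
    ]
    return {
        "normal_night": base(),
        "moderate_sa": base(event_schedule=_mixed_schedule(duration_s, 20.0)),
        "severe_sa": base(event_schedule=_mixed_schedule(duration_s, 45.0)),
        "posture_switcher": base(
            event_schedule=_mixed_schedule(duration_s, 20.0),
            respiratory_axis_schedule=rotations,
        ),
        "noisy": base(
            event_schedule=_mixed_schedule(duration_s, 20.0),
            noise=NoiseSpec(
                pulse_band_amp=6.0, movement_band_amp=15.0, hf_band_amp=4.0, white_sd=3.0
            ),
        ),
    }


def get_preset(
    name: str,
    duration_s: float = 3600.0,
    sampling_rate_hz: float = 32.0,
    seed: int = 0,
) -> ScenarioSpec:
    presets = scenario_presets(duration_s, sampling_rate_hz, seed)
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(sorted(presets))}")
    return presets[name]
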