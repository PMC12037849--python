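"""Respiratory signal extraction from band-limited IMU axes.

Pipeline: per-axis zero-phase FIR band-pass (0.13–0.7 Hz) -> scalar
respiratory amplitude (Euclidean norm of the three filtered axes) ->
dominant-axis waveform stitched per 30-s epoch with polarity continuity ->
piecewise-constant respiratory frequency from negative-to-positive zero
crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve, firwin

EPOCH_SECONDS = 30.0
#: Minimum accepted respiratory cycle length: 1 / high-cut frequency.
MIN_CYCLE_S = 1.0 / 0.7


@dataclass
class FilterSpec:
    """Linear-phase FIR band-pass specification.

    The default tap count spans ~8 cycles of the low cutoff so the stopband
    below 0.13 Hz is usable; the symmetric kernel is applied twice (forward
    convolution with a symmetric FIR is already zero-phase; the second pass
    squares the magnitude response, deepening the stopband).
    """

    sampling_rate_hz: float
    low_cut_hz: float = 0.13
    high_cut_hz: float = 0.7
    n_taps: int | None = None
    design_window: str = "hamming"

    def __post_init__(self) -> None:
        nyq = self.sampling_rate_hz / 2.0
        if not (0 < self.low_cut_hz < self.high_cut_hz < nyq):
            raise ValueError(
                f"need 0 < low ({self.low_cut_hz}) < high ({self.high_cut_hz}) "
                f"< Nyquist ({nyq})"
            )
        if self.n_taps is None:
            n = int(round(8.0 * self.sampling_rate_hz / self.low_cut_hz))
            self.n_taps = n if n % 2 == 1 else n + 1
        if self.n_taps % 2 == 0 or self.n_taps <= 0:
            raise ValueError("n_taps must be a positive odd integer")

    def taps(self) -> np.ndarray:
        return firwin(
            self.n_taps,
            [self.low_cut_hz, self.high_cut_hz],
            pass_zero=False,
            window=self.design_window,
            fs=self.sampling_rate_hz,
        )


@dataclass
class RespiratoryAmplitudeSeries:
    """Per-sample respiratory movement amplitude (non-negative scalar)."""

    values: np.ndarray
    sampling_rate_hz: float
    channel: str = "acceleration"


@dataclass
class RespiratoryWaveform:
    """Dominant-axis respiratory waveform after polarity-stitched concatenation."""

    values: np.ndarray
    sampling_rate_hz: float
    epoch_axis_choices: np.ndarray
    epoch_polarity: np.ndarray


@dataclass
class RespiratoryFrequencySeries:
    """Piecewise-constant instantaneous respiratory frequency in Hz."""

    values: np.ndarray
    sampling_rate_hz: float
    cycle_boundaries_s: np.ndarray


def bandpass_axis(axis_signal: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase band-pass of one axis; output has the input's length."""
    x = np.asarray(axis_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("axis signal must be 1-D")
    if len(x) <= spec.n_taps:
        raise ValueError(
            f"signal length {len(x)} must exceed filter length {spec.n_taps}"
        )
    b = spec.taps()
    y = _zero_phase_pass(x, b)
    return _zero_phase_pass(y, b)


def _zero_phase_pass(x: np.ndarray, b: np.ndarray) -> np.ndarray:
    """One zero-phase pass of a symmetric FIR.

    The symmetric kernel with mode='same' compensates the (n_taps-1)/2 group
    delay exactly; odd-reflection padding (as in filtfilt) keeps the signal
    level up at the recording edges instead of tapering toward zero.
    """
    pad = min(len(x) - 1, len(b) // 2)
    left = 2 * x[0] - x[pad:0:-1]
    right = 2 * x[-1] - x[-2 : -pad - 2 : -1]
    padded = np.concatenate([left, x, right])
    return fftconvolve(padded, b, mode="same")[pad : pad + len(x)]


def respiratory_amplitude(
    filtered_x: np.ndarray,
    filtered_y: np.ndarray,
    filtered_z: np.ndarray,
    sampling_rate_hz: float,
    channel: str = "acceleration",
) -> RespiratoryAmplitudeSeries:
    """Element-wise Euclidean norm of the three filtered axes."""
    fx, fy, fz = (np.asarray(a, dtype=float) for a in (filtered_x, filtered_y, filtered_z))
    if not (fx.shape == fy.shape == fz.shape):
        raise ValueError("axis lengths differ")
    ra = np.sqrt(fx**2 + fy**2 + fz**2)
    return RespiratoryAmplitudeSeries(ra, sampling_rate_hz, channel)


def _epoch_slices(n: int, sampling_rate_hz: float, epoch_s: float) -> list[slice]:
    step = int(round(epoch_s * sampling_rate_hz))
    return [slice(i, min(i + step, n)) for i in range(0, n, step)]


def select_dominant_axes(
    filtered_xyz: np.ndarray, sampling_rate_hz: float, epoch_s: float = EPOCH_SECONDS
) -> np.ndarray:
    """Per-epoch index of the axis with the largest excursion (max - min).

    Ties resolve to the lowest axis index. The final partial epoch is scored
    over its actual length.
    """
    fxyz = np.asarray(filtered_xyz, dtype=float)
    if fxyz.ndim != 2 or fxyz.shape[0] != 3:
        raise ValueError("filtered_xyz must have shape (3, N)")
    choices = []
    for sl in _epoch_slices(fxyz.shape[1], sampling_rate_hz, epoch_s):
        seg = fxyz[:, sl]
        ranges = seg.max(axis=1) - seg.min(axis=1)
        choices.append(int(np.argmax(ranges)))  # argmax takes lowest on ties
    return np.asarray(choices, dtype=int)


def build_respiratory_waveform(
    filtered_xyz: np.ndarray,
    axis_choices: np.ndarray,
    spec: FilterSpec,
    epoch_s: float = EPOCH_SECONDS,
) -> RespiratoryWaveform:
    """Concatenate per-epoch dominant-axis segments with polarity continuity.

    Each epoch's sign is chosen to minimize the jump between the last sample
    of the already-stitched waveform and the first sample of the signed new
    segment (ties -> +1); the stitched series is then re-filtered with the
    same band-pass to remove junction artifacts.
    """
    fxyz = np.asarray(filtered_xyz, dtype=float)
    slices = _epoch_slices(fxyz.shape[1], spec.sampling_rate_hz, epoch_s)
    if len(axis_choices) != len(slices):
        raise ValueError("axis_choices length does not match epoch count")

    polarity = np.ones(len(slices), dtype=int)
    pieces: list[np.ndarray] = []
    last = None
    for k, sl in enumerate(slices):
        seg = fxyz[axis_choices[k], sl]
        if k > 0 and axis_choices[k] == axis_choices[k - 1]:
            # same axis: the segment continues the previous one exactly, so a
            # sign flip could only manufacture a junction discontinuity
            polarity[k] = polarity[k - 1]
        elif last is not None:
            if abs(last - (-seg[0])) < abs(last - seg[0]):
                polarity[k] = -1
        piece = polarity[k] * seg
        pieces.append(piece)
        last = piece[-1]
    stitched = np.concatenate(pieces)
    values = bandpass_axis(stitched, spec)
    return RespiratoryWaveform(values, spec.sampling_rate_hz, np.asarray(axis_choices), polarity)


def respiratory_frequency(
    waveform: RespiratoryWaveform, min_cycle_s: float = MIN_CYCLE_S
) -> RespiratoryFrequencySeries:
    """Step-interpolated breathing frequency from upward zero crossings.

    Crossing times are localized by linear interpolation between bracketing
    samples; intervals shorter than ``min_cycle_s`` (residual ripple) are
    merged into the following cycle. Samples before the first / after the
    last crossing take the nearest defined cycle value.
    """
    w = np.asarray(waveform.values, dtype=float)
    fs = waveform.sampling_rate_hz
    idx = np.nonzero((w[:-1] < 0) & (w[1:] >= 0))[0]
    if len(idx) < 2:
        raise ValueError("no respiratory cycles detected")
    frac = -w[idx] / (w[idx + 1] - w[idx])
    crossings = (idx + frac) / fs

    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= min_cycle_s:
            kept.append(c)
    boundaries = np.asarray(kept)
    if len(boundaries) < 2:
        raise ValueError("no respiratory cycles detected")

    cycle_len = np.diff(boundaries)
    freqs = 1.0 / cycle_len
    t = np.arange(len(w)) / fs
    # sample i belongs to the cycle whose boundary interval contains t[i]
    pos = np.clip(np.searchsorted(boundaries, t, side="right") - 1, 0, len(freqs) - 1)
    return RespiratoryFrequencySeries(freqs[pos], fs, boundaries)


def bridge_gaps(signal: np.ndarray, gap_mask: np.ndarray) -> np.ndarray:
    """Linearly interpolate across masked samples on the uniform time base."""
    x = np.asarray(signal, dtype=float).copy()
    gap = np.asarray(gap_mask, dtype=bool)
    if not gap.any():
        return x
    if gap.all():
        raise ValueError("cannot bridge a fully masked signal")
    idx = np.arange(len(x))
    x[gap] = np.interp(idx[gap], idx[~gap], x[~gap])
    return x
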