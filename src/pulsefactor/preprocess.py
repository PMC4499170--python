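"""Cleaning and segmentation of raw tonometric pulse signals.

The chain is: zero-phase band-pass filtering (default 0.5–20 Hz, wide
enough for the heart harmonics and the 0–13 Hz spectral band), beat
onset detection at the waveform foot, cubic-spline baseline-wander
removal anchored at the feet, beat segmentation, and selection of the
hold-down pressure step with maximal pulse amplitude (whose displacement
is the PDI factor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, find_peaks, sosfiltfilt

from .synthetic import PressureSweepRecording

# Low corner keeps 40-bpm fundamentals flat; high corner sits well above
# the beat's harmonic content so sharp feet/notches are not smeared.
DEFAULT_BAND = (0.3, 35.0)  # Hz

__all__ = [
    "CleanBeatTrain",
    "InsufficientBeatsError",
    "bandpass_filter",
    "detect_beat_onsets",
    "remove_baseline_spline",
    "segment_beats",
    "clean_beat_train",
    "select_pressure_step",
]

MIN_HR, MAX_HR = 40.0, 180.0


class InsufficientBeatsError(ValueError):
    """Fewer than three beats could be detected in the signal."""


@dataclass
class CleanBeatTrain:
    """A detrended single-step pulse signal with its beat onsets."""

    signal: np.ndarray  # V, zero baseline at the beat feet
    sample_rate: float  # Hz
    onsets: np.ndarray  # sample indices, strictly increasing
    heart_rate: float  # bpm, median inter-onset rate
    source_step: int = 0
    displacement: float = 0.0  # mm


def bandpass_filter(
    signal, sample_rate: float, low: float = DEFAULT_BAND[0], high: float = DEFAULT_BAND[1]
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, order 4).

    Zero-phase filtering keeps beat landmarks unshifted.  ``low = 0``
    degenerates to a low-pass.
    """
    nyq = sample_rate / 2.0
    if not (0 <= low < high < nyq):
        raise ValueError(f"band [{low}, {high}] Hz outside (0, Nyquist={nyq}) Hz")
    x = np.asarray(signal, dtype=float)
    if low > 0:
        sos = butter(4, [low, high], btype="bandpass", fs=sample_rate, output="sos")
    else:
        sos = butter(4, high, btype="lowpass", fs=sample_rate, output="sos")
    return sosfiltfilt(sos, x)


def detect_beat_onsets(signal, sample_rate: float) -> np.ndarray:
    """Locate one onset per beat at the waveform foot.

    The foot is the minimum preceding each maximal upstroke slope.
    Upstrokes are found as prominent peaks of the first derivative,
    separated by at least the shortest plausible beat (180 bpm).
    """
    x = np.asarray(signal, dtype=float)
    d = np.gradient(x) * sample_rate
    dmax = d.max()
    if dmax <= 0:
        raise InsufficientBeatsError("insufficient beats: no upstrokes found")
    min_dist = max(int(60.0 / MAX_HR * sample_rate), 1)
    peaks, _ = find_peaks(d, height=0.4 * dmax, distance=min_dist)
    if len(peaks) < 3:
        raise InsufficientBeatsError(f"insufficient beats: {len(peaks)} upstrokes")
    interval = float(np.median(np.diff(peaks)))
    back = max(int(0.5 * interval), 2)
    onsets = []
    n = len(x)
    for p in peaks:
        lo = max(p - back, 0)
        win = x[lo : p + 1]
        amp = float(x[lo : min(p + back, n)].max() - win.min())
        # last sample before the upstroke still within 4% of the local
        # minimum, then walk back to the nearest local minimum: the foot
        thr = win.min() + 0.04 * amp
        below = np.nonzero(win <= thr)[0]
        j = lo + int(below[-1]) if len(below) else lo
        while j > lo and x[j - 1] <= x[j]:
            j -= 1
        onsets.append(j)
    onsets = np.unique(np.asarray(onsets, dtype=int))
    if len(onsets) < 3:
        raise InsufficientBeatsError("insufficient beats after foot search")
    return onsets


def remove_baseline_spline(signal, sample_rate: float, onsets) -> np.ndarray:
    """Subtract a cubic spline through the beat-foot anchor points.

    Baseline wander from breathing and slow motion rides on the beat
    feet; interpolating the foot values and subtracting re-anchors every
    onset to ~0 V.  Needs at least 3 anchors.
    """
    onsets = np.asarray(onsets, dtype=int)
    if len(onsets) < 3:
        raise ValueError("need at least 3 onset anchors for the baseline spline")
    x = np.asarray(signal, dtype=float)
    spline = CubicSpline(onsets.astype(float), x[onsets], extrapolate=True)
    return x - spline(np.arange(len(x), dtype=float))


def segment_beats(train: CleanBeatTrain) -> tuple[list[np.ndarray], np.ndarray]:
    """Split into half-open per-beat spans [onset_i, onset_{i+1}).

    Returns the beats plus the per-beat heart rate in bpm.
    """
    o = train.onsets
    beats = [train.signal[o[i] : o[i + 1]] for i in range(len(o) - 1)]
    hr = 60.0 * train.sample_rate / np.diff(o)
    return beats, hr


def clean_beat_train(
    signal,
    sample_rate: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    source_step: int = 0,
    displacement: float = 0.0,
) -> CleanBeatTrain:
    """Run the full cleaning chain on one pressure step's signal."""
    filtered = bandpass_filter(signal, sample_rate, low, high)
    onsets = detect_beat_onsets(filtered, sample_rate)
    detrended = remove_baseline_spline(filtered, sample_rate, onsets)
    intervals = np.diff(onsets) / sample_rate
    heart_rate = float(60.0 / np.median(intervals))
    if not (MIN_HR <= heart_rate <= MAX_HR):
        raise InsufficientBeatsError(
            f"implausible median heart rate {heart_rate:.1f} bpm"
        )
    return CleanBeatTrain(
        signal=detrended,
        sample_rate=sample_rate,
        onsets=onsets,
        heart_rate=heart_rate,
        source_step=source_step,
        displacement=displacement,
    )


def select_pressure_step(
    rec: PressureSweepRecording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
) -> tuple[int, float, CleanBeatTrain]:
    """Pick the hold-down step with maximal pulse amplitude.

    Every step is cleaned independently; the winner maximises the median
    per-beat peak-to-foot amplitude (ties to the smaller displacement).
    The winning displacement (step index × step size) is the PDI.  If
    the amplitude peaks at the deepest step the sweep may not have
    bracketed the true maximum, which is warned about.
    """
    if rec.n_steps < 3:
        raise ValueError("need at least 3 pressure steps")
    trains: dict[int, CleanBeatTrain] = {}
    amps: dict[int, float] = {}
    for s in range(rec.n_steps):
        try:
            train = clean_beat_train(
                rec.signal[s],
                rec.sample_rate,
                low,
                high,
                source_step=s,
                displacement=s * rec.step_displacement_mm,
            )
        except (InsufficientBeatsError, ValueError):
            continue
        beats, _ = segment_beats(train)
        amps[s] = float(np.median([b.max() - b[0] for b in beats]))
        trains[s] = train
    if not trains:
        raise InsufficientBeatsError("beat detection failed on every pressure step")
    best = min(amps, key=lambda s: (-amps[s], s))  # ties -> smaller displacement
    if best == rec.n_steps - 1:
        warnings.warn(
            "sweep did not bracket maximum: amplitude peaks at the deepest step",
            stacklevel=2,
        )
    return best, best * rec.step_displacement_mm, trains[best]
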