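"""The ten physical factors of a wrist pulse recording.

Time-domain factors: PPI (peak-to-foot pulse amplitude, V), PDI (sensor
displacement at maximal pulse pressure, mm), the four area sums over the
regions where the waveform exceeds 30% of PPI or the 1.12 V detection
voltage (V·s, totalled over all beats of the analysed window), and the
systolic area normalised to a 75 bpm heart rate (Asys-HR75, V·s).
Frequency-domain factors from a Welch power spectral density: the
density at the first and second heart-rate harmonics (Vrms²/Hz) and the
integrated 0–13 Hz band power (Vrms²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .params import FACTOR_NAMES
from .preprocess import CleanBeatTrain, segment_beats, select_pressure_step
from .synthetic import PressureSweepRecording, feature_columns

DETECTION_VOLTAGE = 1.12  # V, absolute device threshold
RELATIVE_THRESHOLD = 0.30  # fraction of PPI
PSD_RESOLUTION = 0.25  # Hz
HARMONIC_SEARCH_HZ = 0.3  # half-width of the harmonic peak search
PSD_BAND = (0.0, 13.0)  # Hz

__all__ = [
    "FeatureVector",
    "PSDSpectrum",
    "compute_ppi",
    "region_areas",
    "sum30p_factors",
    "sum112v_factors",
    "detect_dicrotic_notch",
    "asys_hr75",
    "compute_psd",
    "harmonic_psd",
    "psd_band_area",
    "extract_features",
    "extract_feature_table",
]


@dataclass
class FeatureVector:
    """The ten physical factors for one wrist of one subject."""

    PPI: float  # V
    PDI: float  # mm
    Sum30p: float  # V·s
    Sum30p_PPI: float  # V·s
    Sum112v: float  # V·s
    Sum112v_PPI: float  # V·s
    Asys_HR75: float  # V·s
    PSD_w1: float  # Vrms²/Hz
    PSD_w2: float  # Vrms²/Hz
    PSD_0_13: float  # Vrms²
    wrist: str = "L"

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FACTOR_NAMES}


@dataclass
class PSDSpectrum:
    """One-sided Welch power spectral density on a uniform grid."""

    frequencies: np.ndarray  # Hz
    density: np.ndarray  # Vrms²/Hz
    resolution: float  # Hz


def compute_ppi(beats) -> float:
    """Median over beats of the peak-to-foot amplitude (V)."""
    if len(beats) == 0:
        raise ValueError("no beats supplied")
    return float(np.median([float(np.max(b)) - float(b[0]) for b in beats]))


def region_areas(signal, sample_rate: float, threshold: float):
    """Areas of the supra-threshold region of a piecewise-linear signal.

    Over the samples where the signal exceeds ``threshold`` (with linear
    interpolation of the crossings):

    * ``s_full``  — ∫ signal dt (V·s),
    * ``s_above`` — ∫ (signal − threshold) dt (V·s),
    * ``t_above`` — total time above (s),

    computed so that ``s_full − s_above == threshold * t_above`` holds to
    machine precision.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    y = np.asarray(signal, dtype=float) - threshold
    dt = 1.0 / sample_rate
    y0, y1 = y[:-1], y[1:]
    s_above = 0.0
    t_above = 0.0
    both = (y0 > 0) & (y1 > 0)
    s_above += np.sum((y0[both] + y1[both])) * 0.5 * dt
    t_above += np.count_nonzero(both) * dt
    enter = (y0 <= 0) & (y1 > 0)
    if np.any(enter):
        frac = y1[enter] / (y1[enter] - y0[enter])
        s_above += float(np.sum(0.5 * y1[enter] * frac) * dt)
        t_above += float(np.sum(frac) * dt)
    leave = (y0 > 0) & (y1 <= 0)
    if np.any(leave):
        frac = y0[leave] / (y0[leave] - y1[leave])
        s_above += float(np.sum(0.5 * y0[leave] * frac) * dt)
        t_above += float(np.sum(frac) * dt)
    s_full = s_above + threshold * t_above
    return float(s_full), float(s_above), float(t_above)


def sum30p_factors(beats, sample_rate: float, ppi: float) -> tuple[float, float]:
    """(Sum-30p, Sum-30p-PPI): totals over all beats, threshold 0.3·PPI."""
    thr = RELATIVE_THRESHOLD * ppi
    s_full = s_above = 0.0
    for b in beats:
        f, a, _ = region_areas(b, sample_rate, thr)
        s_full += f
        s_above += a
    return s_full, s_above


def sum112v_factors(
    beats, sample_rate: float, threshold: float = DETECTION_VOLTAGE
) -> tuple[float, float]:
    """(Sum-1.12v, Sum-1.12v-PPI): totals with the absolute device threshold."""
    s_full = s_above = 0.0
    for b in beats:
        f, a, _ = region_areas(b, sample_rate, threshold)
        s_full += f
        s_above += a
    return s_full, s_above


def detect_dicrotic_notch(beat, sample_rate: float) -> int:
    """First local minimum after the systolic peak, within 60% of the beat.

    A beat without such a minimum (e.g. a monotone or single-bump wave)
    falls back to 40% of the beat duration, with a warning.
    """
    b = np.asarray(beat, dtype=float)
    n = len(b)
    pk = int(np.argmax(b))
    hi = int(0.6 * n)
    seg = b[pk : hi + 1]
    d = np.diff(seg)
    mins = np.where((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
    if len(mins) > 0:
        return pk + int(mins[0])
    warnings.warn("no dicrotic notch found; using the 40%-of-beat fallback", stacklevel=2)
    return int(round(0.40 * n))


def asys_hr75(beat, sample_rate: float, heart_rate: float) -> float:
    """Systolic area (onset → dicrotic notch) normalised to 75 bpm.

    Rescaling the time axis so the beat lasts 60/75 s multiplies the
    area by heart_rate/75.
    """
    if not (40.0 <= heart_rate <= 180.0):
        raise ValueError("heart_rate must be in [40, 180] bpm")
    b = np.asarray(beat, dtype=float)
    notch = detect_dicrotic_notch(b, sample_rate)
    raw = float(np.trapezoid(b[: notch + 1], dx=1.0 / sample_rate))
    return raw * heart_rate / 75.0


def compute_psd(signal, sample_rate: float) -> PSDSpectrum:
    """Welch PSD: Hann window, 50% overlap, ≤0.25 Hz resolution, one-sided."""
    x = np.asarray(signal, dtype=float)
    if len(x) < 10 * sample_rate:
        raise ValueError("need at least 10 s of signal for the PSD")
    nperseg = min(int(np.ceil(sample_rate / PSD_RESOLUTION)), len(x))
    freqs, dens = welch(
        x,
        fs=sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        scaling="density",
    )
    return PSDSpectrum(
        frequencies=freqs, density=dens, resolution=float(freqs[1] - freqs[0])
    )


def harmonic_psd(psd: PSDSpectrum, heart_rate: float) -> tuple[float, float]:
    """PSD at the first and second heart-rate harmonics.

    Each harmonic is the maximal density within ±0.3 Hz of the nominal
    frequency (heart_rate/60 and its double).
    """
    fmax = psd.frequencies[-1]
    out = []
    for mult in (1, 2):
        fc = mult * heart_rate / 60.0
        if fc - HARMONIC_SEARCH_HZ > fmax:
            raise ValueError(f"harmonic at {fc:.2f} Hz above the spectral grid")
        win = np.abs(psd.frequencies - fc) <= HARMONIC_SEARCH_HZ
        out.append(float(psd.density[win].max()))
    return out[0], out[1]


def psd_band_area(psd: PSDSpectrum, f_lo: float, f_hi: float) -> float:
    """Trapezoidal integral of the density over [f_lo, f_hi] (Vrms²)."""
    f = psd.frequencies
    if not (0 <= f_lo <= f_hi <= f[-1]):
        raise ValueError("band must satisfy 0 <= f_lo <= f_hi <= grid max")
    if f_lo == f_hi:
        return 0.0
    inner = (f > f_lo) & (f < f_hi)
    grid = np.concatenate(([f_lo], f[inner], [f_hi]))
    dens = np.concatenate(
        (
            [np.interp(f_lo, f, psd.density)],
            psd.density[inner],
            [np.interp(f_hi, f, psd.density)],
        )
    )
    return float(np.trapezoid(dens, grid))


def _train_features(train: CleanBeatTrain, pdi: float, wrist: str) -> FeatureVector:
    beats, beat_hrs = segment_beats(train)
    if len(beats) >= 5:
        # the first and last beats sit in the zero-phase filter's edge
        # transients; drop them when enough beats remain
        beats, beat_hrs = beats[1:-1], beat_hrs[1:-1]
    ppi = compute_ppi(beats)
    sum30, sum30_ppi = sum30p_factors(beats, train.sample_rate, ppi)
    sum112, sum112_ppi = sum112v_factors(beats, train.sample_rate)
    # median: a beat-level average immune to occasional segmentation
    # glitches (split or merged beats)
    asys = float(
        np.median(
            [
                asys_hr75(b, train.sample_rate, float(np.clip(hr, 40.0, 180.0)))
                for b, hr in zip(beats, beat_hrs)
            ]
        )
    )
    psd = compute_psd(train.signal, train.sample_rate)
    w1, w2 = harmonic_psd(psd, train.heart_rate)
    band = psd_band_area(psd, *PSD_BAND)
    return FeatureVector(
        PPI=ppi,
        PDI=pdi,
        Sum30p=sum30,
        Sum30p_PPI=sum30_ppi,
        Sum112v=sum112,
        Sum112v_PPI=sum112_ppi,
        Asys_HR75=asys,
        PSD_w1=w1,
        PSD_w2=w2,
        PSD_0_13=band,
        wrist=wrist,
    )


def extract_features(rec: PressureSweepRecording, wrist: str | None = None) -> FeatureVector:
    """Compute the ten factors from one pressure-sweep recording.

    Runs the cleaning chain per step, selects the maximal-amplitude step
    (whose displacement is the PDI), and evaluates every factor on that
    step's beat train.
    """
    wrist = wrist or rec.wrist
    _, pdi, train = select_pressure_step(rec)
    return _train_features(train, pdi, wrist)


def extract_feature_table(
    recordings: dict[str, dict[str, PressureSweepRecording]],
    demographics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Batch feature extraction over a cohort of recordings.

    Returns one row per subject with the canonical CSV columns; missing
    demographics are left as NaN (and the label empty) unless a
    ``demographics`` frame indexed by subject id provides them.
    """
    rows = []
    for sid in sorted(recordings):
        row: dict[str, object] = {"id": sid}
        for wrist, rec in sorted(recordings[sid].items()):
            fv = extract_features(rec, wrist=wrist)
            for name, value in fv.as_dict().items():
                row[f"{wrist}_{name}"] = value
        if demographics is not None and sid in demographics.index:
            for col in ("age", "bmi", "sbp", "dbp", "label"):
                if col in demographics.columns:
                    row[col] = demographics.loc[sid, col]
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in feature_columns():
        if col not in df.columns:
            df[col] = np.nan
    return df[feature_columns()]
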