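"""Synthetic tonometric pulse recordings and cohort feature tables.

Two simulators live here.  The waveform simulator produces pressure-sweep
recordings — one multi-beat pulse signal per hold-down step, with
baseline wander and sensor noise — together with a truth manifest of the
planted factor values, so the preprocessing and feature-extraction
stages can be validated against known ground truth.  The cohort
simulator draws per-subject factor tables from per-class Gaussian
marginals whose defaults equal the published means/SDs of the reference
cohort (341 normotensive / 52 hypertensive women), which is what the
association and prediction stages are benchmarked on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .params import (
    FACTOR_NAMES,
    BeatModelParams,
    CohortSpec,
    ParameterError,
    SweepParams,
)

__all__ = [
    "PressureSweepRecording",
    "TruthEntry",
    "generate_beat_template",
    "generate_recording",
    "generate_cohort_features",
    "generate_cohort_recordings",
    "feature_columns",
    "write_recordings_h5",
    "read_recordings_h5",
]


@dataclass
class PressureSweepRecording:
    """Raw multi-step pulse signal for one wrist of one subject.

    ``signal`` has shape (n_steps, n_samples): one channel per
    hold-down displacement step, in volts.
    """

    signal: np.ndarray
    sample_rate: float  # Hz
    step_displacement_mm: float
    subject_id: str = "s0"
    wrist: str = "L"

    @property
    def n_steps(self) -> int:
        return self.signal.shape[0]


@dataclass
class TruthEntry:
    """Planted ground truth for one generated recording."""

    subject_id: str
    wrist: str
    ppi: float  # V
    pdi: float  # mm
    asys_hr75: float  # V·s, systolic area normalised to 75 bpm
    heart_rate: float  # bpm
    label: str  # "normotensive" | "hypertensive"


def _gauss(t: np.ndarray | float, p: float, w: float):
    return np.exp(-((t - p) ** 2) / (2.0 * w * w))


def _dgauss(t: float, p: float, w: float) -> float:
    return -(t - p) / (w * w) * math.exp(-((t - p) ** 2) / (2.0 * w * w))


def generate_beat_template(
    params: BeatModelParams, sample_rate: float
) -> np.ndarray:
    """Sample one beat of the three-lobe pulse model.

    Returns a waveform of duration ``60/heart_rate`` seconds whose first
    and last samples are exactly 0 V and whose global maximum equals
    ``amplitude_scale``.  The dicrotic lobe height is chosen so the
    waveform is stationary (the notch) at ``notch_position`` of the beat.
    """
    if sample_rate < 100.0:
        raise ParameterError("sample_rate: must be >= 100 Hz")
    duration = 60.0 / params.heart_rate
    n = int(round(duration * sample_rate))
    # fraction-of-beat grid; last sample sits just short of 1
    t = np.arange(n) / n
    t_last = t[-1]

    (p1, p2, p3) = params.lobe_positions
    (w1, w2, w3) = params.lobe_widths
    (h1, h2, h3_nominal) = params.lobe_heights
    nt = params.notch_position

    g12 = h1 * _gauss(t, p1, w1) + h2 * _gauss(t, p2, w2)
    g3 = _gauss(t, p3, w3)
    # Dicrotic height solved so the waveform is stationary at the notch.
    d12 = h1 * _dgauss(nt, p1, w1) + h2 * _dgauss(nt, p2, w2)
    d3 = _dgauss(nt, p3, w3)
    h3 = -d12 / d3 if abs(d3) > 1e-12 else h3_nominal
    if h3 <= 0:  # constraint unsatisfiable for these lobes; fall back
        h3 = h3_nominal
    g = g12 + h3 * g3
    # Remove the small percussion-tail offset at the beat start with a
    # fast-decaying Gaussian so the waveform leaves 0 V exactly (with a
    # smooth takeoff) and never dips below the foot; the lobe tails
    # already vanish at the beat end.  The correction is ~e^-90 at the
    # notch, so the planted notch location is unaffected.
    g = g - g[0] * np.exp(-((t / 0.046) ** 2))
    g *= params.amplitude_scale / g.max()
    return g


def _beat_train(
    params: BeatModelParams,
    sample_rate: float,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Concatenate beats (with per-beat heart-rate jitter) to length."""
    out = np.empty(n_samples)
    pos = 0
    while pos < n_samples:
        if params.hr_jitter_sd > 0:
            hr = float(
                np.clip(
                    params.heart_rate + rng.normal(0.0, params.hr_jitter_sd),
                    40.0,
                    180.0,
                )
            )
            beat_params = BeatModelParams(
                amplitude_scale=params.amplitude_scale,
                lobe_positions=params.lobe_positions,
                lobe_widths=params.lobe_widths,
                lobe_heights=params.lobe_heights,
                notch_position=params.notch_position,
                heart_rate=hr,
                hr_jitter_sd=0.0,
            )
        else:
            beat_params = params
        beat = generate_beat_template(beat_params, sample_rate)
        m = min(len(beat), n_samples - pos)
        out[pos : pos + m] = beat[:m]
        pos += m
    return out


def planted_systolic_area(params: BeatModelParams, sample_rate: float) -> float:
    """Systolic area (onset→notch, V·s) of the clean template, HR75-normalised."""
    beat = generate_beat_template(params, sample_rate)
    n = len(beat)
    notch_idx = int(round(params.notch_position * n))
    raw = float(np.trapezoid(beat[: notch_idx + 1], dx=1.0 / sample_rate))
    return raw * params.heart_rate / 75.0


def generate_recording(
    beat: BeatModelParams,
    sweep: SweepParams,
    seed: int | np.random.Generator,
    subject_id: str = "s0",
    wrist: str = "L",
    label: str = "normotensive",
) -> tuple[PressureSweepRecording, TruthEntry]:
    """Simulate one pressure-sweep recording plus its truth entry.

    Per-step pulse amplitude follows a Gaussian profile over step index,
    peaking (relative amplitude 1) at ``sweep.optimal_step``; a drift
    sinusoid and white noise are added to every step.
    """
    if sweep.duration < 3 * 60.0 / beat.heart_rate:
        raise ParameterError("duration: too short to contain 3 beats")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = sweep.sample_rate
    n_samples = int(round(sweep.duration * fs))
    tsec = np.arange(n_samples) / fs

    steps = np.arange(sweep.n_steps)
    profile = np.exp(
        -((steps - sweep.optimal_step) ** 2)
        / (2.0 * sweep.amplitude_profile_width**2)
    )
    signal = np.empty((sweep.n_steps, n_samples))
    for s in steps:
        train = _beat_train(beat, fs, n_samples, rng)
        drift = sweep.drift_amplitude * np.sin(2 * np.pi * sweep.drift_freq * tsec)
        noise = rng.normal(0.0, sweep.noise_sd, n_samples) if sweep.noise_sd > 0 else 0.0
        signal[s] = profile[s] * train + drift + noise

    rec = PressureSweepRecording(
        signal=signal,
        sample_rate=fs,
        step_displacement_mm=sweep.step_displacement,
        subject_id=subject_id,
        wrist=wrist,
    )
    truth = TruthEntry(
        subject_id=subject_id,
        wrist=wrist,
        ppi=beat.amplitude_scale,
        pdi=sweep.optimal_step * sweep.step_displacement,
        asys_hr75=planted_systolic_area(beat, fs),
        heart_rate=beat.heart_rate,
        label=label,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort-level feature tables


def feature_columns() -> list[str]:
    """Exact column order of the cohort feature CSV."""
    cols = ["id", "age", "bmi", "sbp", "dbp", "label"]
    for wrist in ("L", "R"):
        cols += [f"{wrist}_{name}" for name in FACTOR_NAMES]
    return cols


def _truncated_pressures(
    rng: np.random.Generator,
    n: int,
    sbp_ms: tuple[float, float],
    dbp_ms: tuple[float, float],
    hypertensive: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (SBP, DBP) pairs consistent with the class's diagnosis rule.

    Rejection sampling against SBP>=140 or DBP>=90 (hypertensive side)
    keeps labels and pressures consistent by construction.
    """
    sbp = np.empty(n)
    dbp = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 16)
        s = rng.normal(sbp_ms[0], sbp_ms[1], m)
        d = rng.normal(dbp_ms[0], dbp_ms[1], m)
        s = np.maximum(s, 60.0)
        d = np.clip(d, 40.0, s - 5.0)  # keep SBP > DBP physiologic
        hyper = (s >= 140.0) | (d >= 90.0)
        ok = hyper if hypertensive else ~hyper
        take = min(int(ok.sum()), n - filled)
        sbp[filled : filled + take] = s[ok][:take]
        dbp[filled : filled + take] = d[ok][:take]
        filled += take
    return sbp, dbp


def generate_cohort_features(
    spec: CohortSpec,
    seed: int | np.random.Generator,
    correlation: float | np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw a per-subject feature table from the per-class marginals.

    Each factor is drawn independently per class from its Gaussian
    marginal (the published summaries carry no covariance).  Optionally,
    ``correlation`` imposes a common Gaussian-copula correlation across
    the 20 factors — either a scalar exchangeable correlation or a full
    20×20 matrix — for feature-selection experiments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    factor_keys = [(w, f) for w in ("L", "R") for f in FACTOR_NAMES]
    for label, n in (("normotensive", spec.n_normo), ("hypertensive", spec.n_hyper)):
        if n == 0:
            continue
        cls = 1 if label == "hypertensive" else 0
        p = len(factor_keys)
        if correlation is None:
            z = rng.standard_normal((n, p))
        else:
            if np.isscalar(correlation):
                corr = np.full((p, p), float(correlation))
                np.fill_diagonal(corr, 1.0)
            else:
                corr = np.asarray(correlation, dtype=float)
            chol = np.linalg.cholesky(corr)
            z = rng.standard_normal((n, p)) @ chol.T
        data = {}
        for j, (w, f) in enumerate(factor_keys):
            m, s = spec.factor_stats[(w, f)][cls]
            data[f"{w}_{f}"] = m + s * z[:, j]
        age_ms = spec.demographic_stats["age"][cls]
        bmi_ms = spec.demographic_stats["bmi"][cls]
        sbp, dbp = _truncated_pressures(
            rng,
            n,
            spec.demographic_stats["sbp"][cls],
            spec.demographic_stats["dbp"][cls],
            hypertensive=(cls == 1),
        )
        df = pd.DataFrame(data)
        df.insert(0, "label", label)
        df.insert(0, "dbp", dbp)
        df.insert(0, "sbp", sbp)
        df.insert(0, "bmi", rng.normal(bmi_ms[0], bmi_ms[1], n))
        df.insert(0, "age", rng.normal(age_ms[0], age_ms[1], n))
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", [f"s{i:04d}" for i in range(len(out))])
    return out[feature_columns()]


def generate_cohort_recordings(
    spec: CohortSpec,
    beat_defaults: BeatModelParams | None = None,
    sweep_defaults: SweepParams | None = None,
    seed: int | np.random.Generator = 0,
    hyper_amplitude_multiplier: float = 1.25,
    amplitude_cv: float = 0.05,
) -> tuple[dict[str, dict[str, PressureSweepRecording]], pd.DataFrame]:
    """Simulate pressure-sweep recordings for a whole cohort.

    Hypertensive subjects get ``hyper_amplitude_multiplier`` times the
    normotensive pulse amplitude (hypertension raises the pulse-pressure
    wave height), with per-subject lognormal variability ``amplitude_cv``.
    Returns ``{subject_id: {"L": rec, "R": rec}}`` plus the truth
    manifest (one row per recording).
    """
    beat_defaults = beat_defaults or BeatModelParams()
    sweep_defaults = sweep_defaults or SweepParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    recordings: dict[str, dict[str, PressureSweepRecording]] = {}
    rows = []
    idx = 0
    for label, n in (("normotensive", spec.n_normo), ("hypertensive", spec.n_hyper)):
        mult = hyper_amplitude_multiplier if label == "hypertensive" else 1.0
        for _ in range(n):
            sid = f"s{idx:04d}"
            idx += 1
            recordings[sid] = {}
            for wrist in ("L", "R"):
                amp = (
                    beat_defaults.amplitude_scale
                    * mult
                    * float(np.exp(rng.normal(0.0, amplitude_cv)))
                    if amplitude_cv > 0
                    else beat_defaults.amplitude_scale * mult
                )
                bp = BeatModelParams(
                    amplitude_scale=amp,
                    lobe_positions=beat_defaults.lobe_positions,
                    lobe_widths=beat_defaults.lobe_widths,
                    lobe_heights=beat_defaults.lobe_heights,
                    notch_position=beat_defaults.notch_position,
                    heart_rate=beat_defaults.heart_rate,
                    hr_jitter_sd=beat_defaults.hr_jitter_sd,
                )
                rec, truth = generate_recording(
                    bp, sweep_defaults, rng, subject_id=sid, wrist=wrist, label=label
                )
                recordings[sid][wrist] = rec
                rows.append(truth.__dict__.copy())
    manifest = pd.DataFrame(rows)
    return recordings, manifest


# ---------------------------------------------------------------------------
# HDF5 layout: /subjects/<id>/wrist{L,R}/signal + /manifest


def write_recordings_h5(
    path,
    recordings: dict[str, dict[str, PressureSweepRecording]],
    manifest: pd.DataFrame | None = None,
) -> None:
    with h5py.File(path, "w", track_order=False) as f:
        subjects = f.create_group("subjects")
        for sid in sorted(recordings):
            g = subjects.create_group(sid)
            for wrist, rec in sorted(recordings[sid].items()):
                wg = g.create_group(f"wrist{wrist}")
                wg.create_dataset("signal", data=rec.signal, track_times=False)
                wg.attrs["sample_rate"] = rec.sample_rate
                wg.attrs["step_displacement_mm"] = rec.step_displacement_mm
        if manifest is not None:
            man = f.create_group("manifest")
            for col in manifest.columns:
                vals = manifest[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                man.create_dataset(col, data=vals, track_times=False)


def read_recordings_h5(path) -> tuple[dict[str, dict[str, PressureSweepRecording]], pd.DataFrame | None]:
    recordings: dict[str, dict[str, PressureSweepRecording]] = {}
    manifest = None
    with h5py.File(path, "r") as f:
        for sid, g in f["subjects"].items():
            recordings[sid] = {}
            for key, wg in g.items():
                wrist = key.removeprefix("wrist")
                recordings[sid][wrist] = PressureSweepRecording(
                    signal=wg["signal"][()],
                    sample_rate=float(wg.attrs["sample_rate"]),
                    step_displacement_mm=float(wg.attrs["step_displacement_mm"]),
                    subject_id=sid,
                    wrist=wrist,
                )
        if "manifest" in f:
            cols = {}
            for col, ds in f["manifest"].items():
                v = ds[()]
                if v.dtype.kind == "S":
                    v = v.astype(str)
                cols[col] = v
            manifest = pd.DataFrame(cols)
    return recordings, manifest
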