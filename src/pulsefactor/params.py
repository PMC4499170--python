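"""Parameter containers for the waveform and cohort simulators.

All parameters carry the units of the tonometric measurement chain:
signal amplitudes in volts (V), sensor hold-down displacement in
millimetres (mm), time in seconds, heart rate in beats per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ParameterError(ValueError):
    """A simulator parameter violates its documented constraint."""


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{name}: {msg}")


@dataclass(frozen=True)
class BeatModelParams:
    """Shape parameters of a single radial-pulse beat.

    The beat is modelled as three positive Gaussian lobes on a zero
    baseline — percussion, tidal and dicrotic waves — whose overlap
    produces the dicrotic notch.  Positions and widths are expressed as
    fractions of the beat duration; heights are relative to the
    percussion wave (fixed at 1).  The dicrotic lobe height is solved
    internally so that the notch (the local minimum between the tidal
    and dicrotic lobes) falls exactly at ``notch_position``;
    ``lobe_heights[2]`` is used only as a fallback when that constraint
    has no positive solution.
    """

    amplitude_scale: float = 3.1  # V, peak-to-foot pulse height
    lobe_positions: tuple[float, float, float] = (0.15, 0.30, 0.55)
    lobe_widths: tuple[float, float, float] = (0.075, 0.110, 0.070)
    lobe_heights: tuple[float, float, float] = (1.0, 0.55, 0.28)
    notch_position: float = 0.44  # fraction of beat duration
    heart_rate: float = 75.0  # bpm
    hr_jitter_sd: float = 0.0  # bpm, per-beat heart-rate jitter

    def __post_init__(self) -> None:
        _require(self.amplitude_scale > 0, "amplitude_scale", "must be > 0")
        p = self.lobe_positions
        _require(len(p) == 3, "lobe_positions", "needs 3 values")
        _require(
            0 < p[0] < p[1] < p[2] < 1,
            "lobe_positions",
            "must be strictly increasing within (0, 1)",
        )
        _require(
            len(self.lobe_widths) == 3 and all(w > 0 for w in self.lobe_widths),
            "lobe_widths",
            "must be 3 positive values",
        )
        _require(
            len(self.lobe_heights) == 3 and all(h > 0 for h in self.lobe_heights),
            "lobe_heights",
            "must be 3 positive values",
        )
        _require(
            p[1] < self.notch_position < p[2],
            "notch_position",
            "must lie between the tidal and dicrotic lobe positions",
        )
        _require(
            40.0 <= self.heart_rate <= 180.0,
            "heart_rate",
            "must be in [40, 180] bpm",
        )
        _require(self.hr_jitter_sd >= 0, "hr_jitter_sd", "must be >= 0")


@dataclass(frozen=True)
class SweepParams:
    """Hold-down pressure sweep of the tonometric sensor.

    The sensor is pressed against the wrist in ``n_steps`` displacement
    steps of ``step_displacement`` mm each; pulse amplitude is unimodal
    in depth and peaks at ``optimal_step`` (a Gaussian profile of width
    ``amplitude_profile_width`` steps).  ``drift_*`` model respiratory
    baseline wander, ``noise_sd`` additive sensor noise.
    """

    n_steps: int = 7
    step_displacement: float = 1.0  # mm per step
    optimal_step: int = 4
    amplitude_profile_width: float = 1.8  # steps
    noise_sd: float = 0.02  # V
    drift_amplitude: float = 0.15  # V
    drift_freq: float = 0.25  # Hz, breathing-band baseline wander
    sample_rate: float = 200.0  # Hz
    duration: float = 30.0  # s per step

    def __post_init__(self) -> None:
        _require(self.n_steps >= 3, "n_steps", "must be >= 3")
        _require(
            0 <= self.optimal_step < self.n_steps,
            "optimal_step",
            "must be in [0, n_steps)",
        )
        _require(self.step_displacement > 0, "step_displacement", "must be > 0")
        _require(self.amplitude_profile_width > 0, "amplitude_profile_width", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.drift_amplitude >= 0, "drift_amplitude", "must be >= 0")
        _require(self.drift_freq > 0, "drift_freq", "must be > 0")
        _require(self.sample_rate >= 100.0, "sample_rate", "must be >= 100 Hz")
        _require(self.duration >= 5.0, "duration", "must be >= 5 s")


#: The ten physical factors of one wrist, in canonical (reporting) order.
FACTOR_NAMES: tuple[str, ...] = (
    "PPI",
    "PDI",
    "Sum30p",
    "Sum30p_PPI",
    "Sum112v",
    "Sum112v_PPI",
    "Asys_HR75",
    "PSD_w1",
    "PSD_w2",
    "PSD_0_13",
)

#: Printed display names for the ten factors (per-wrist prefix added separately).
FACTOR_DISPLAY: dict[str, str] = {
    "PPI": "PPI",
    "PDI": "PDI",
    "Sum30p": "Sum-30p",
    "Sum30p_PPI": "Sum-30p-PPI",
    "Sum112v": "Sum-1.12v",
    "Sum112v_PPI": "Sum-1.12v-PPI",
    "Asys_HR75": "Asys-HR75",
    "PSD_w1": "PSD-w1",
    "PSD_w2": "PSD-w2",
    "PSD_0_13": "PSD-0-13Hz",
}

# Published per-class mean (SD) of each factor in the reference cohort of
# 393 Korean women (341 normotensive, 52 hypertensive), Gwan position.
# Keys: (wrist, factor) -> ((mean_normo, sd_normo), (mean_hyper, sd_hyper)).
REFERENCE_FACTOR_STATS: dict[tuple[str, str], tuple[tuple[float, float], tuple[float, float]]] = {
    ("L", "PPI"): ((3.101, 0.667), (3.666, 0.864)),
    ("L", "PDI"): ((6.0, 1.709), (6.005, 1.823)),
    ("L", "Sum30p"): ((85.93, 40.19), (99.55, 49.78)),
    ("L", "Sum30p_PPI"): ((54.78, 25.61), (61.65, 29.59)),
    ("L", "Sum112v"): ((82.7, 41.23), (98.58, 51.61)),
    ("L", "Sum112v_PPI"): ((51.54, 26.97), (60.68, 31.76)),
    ("L", "Asys_HR75"): ((43.02, 3.749), (42.86, 3.214)),
    ("L", "PSD_w1"): ((43.63, 8.169), (47.67, 8.837)),
    ("L", "PSD_w2"): ((10.56, 2.002), (11.5, 2.091)),
    ("L", "PSD_0_13"): ((21.41, 1.919), (22.36, 1.663)),
    ("R", "PPI"): ((3.142, 0.693), (3.979, 0.992)),
    ("R", "PDI"): ((5.909, 1.737), (6.394, 2.196)),
    ("R", "Sum30p"): ((83.02, 35.14), (108.8, 48.24)),
    ("R", "Sum30p_PPI"): ((52.58, 21.48), (70.68, 32.82)),
    ("R", "Sum112v"): ((79.92, 35.85), (108.7, 50.34)),
    ("R", "Sum112v_PPI"): ((49.48, 22.27), (70.48, 35.33)),
    ("R", "Asys_HR75"): ((43.16, 4.031), (43.88, 3.981)),
    ("R", "PSD_w1"): ((41.63, 8.362), (46.22, 8.837)),
    ("R", "PSD_w2"): ((9.984, 1.972), (10.73, 2.149)),
    ("R", "PSD_0_13"): ((20.85, 2.212), (22.25, 2.359)),
}

#: Published per-class mean (SD) of the demographics, same cohort.
REFERENCE_DEMOGRAPHIC_STATS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "age": ((56.9, 5.525), (59.154, 5.782)),
    "bmi": ((24.063, 2.909), (24.823, 3.052)),
    "sbp": ((113.9, 11.95), (148.2, 11.4)),
    "dbp": ((70.45, 7.993), (85.6, 8.132)),
}


def _default_factor_stats():
    return dict(REFERENCE_FACTOR_STATS)


def _default_demo_stats():
    return dict(REFERENCE_DEMOGRAPHIC_STATS)


@dataclass(frozen=True)
class CohortSpec:
    """Per-class Gaussian marginals of the simulated cohort.

    Defaults reproduce the reference cohort: 341 normotensive and 52
    hypertensive women with the published per-class factor and
    demographic means/SDs.  Factor units: V (PPI), mm (PDI), V·s
    (areas), Vrms²/Hz (harmonic PSD), Vrms² (band power).
    """

    n_normo: int = 341
    n_hyper: int = 52
    factor_stats: dict = field(default_factory=_default_factor_stats)
    demographic_stats: dict = field(default_factory=_default_demo_stats)

    def __post_init__(self) -> None:
        _require(self.n_normo >= 0, "n_normo", "must be >= 0")
        _require(self.n_hyper >= 0, "n_hyper", "must be >= 0")
        _require(self.n_normo + self.n_hyper > 0, "n_normo+n_hyper", "must be > 0")
        # sd == 0 is tolerated as a degenerate (constant) marginal
        for key, ((m0, s0), (m1, s1)) in {
            **self.factor_stats,
            **self.demographic_stats,
        }.items():
            _require(s0 >= 0 and s1 >= 0, str(key), "SDs must be >= 0")

    def class_stats(self, wrist: str, factor: str) -> tuple[tuple[float, float], tuple[float, float]]:
        return self.factor_stats[(wrist, factor)]
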