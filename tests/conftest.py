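import numpy as np
import pytest

from pulsefactor.params import BeatModelParams, CohortSpec, SweepParams
from pulsefactor.synthetic import generate_cohort_features, generate_recording

FS = 200.0


@pytest.fixture(scope="session")
def beat_params():
    return BeatModelParams(amplitude_scale=3.0, heart_rate=75.0)


@pytest.fixture(scope="session")
def clean_sweep():
    """Noise- and drift-free sweep: planted truth is exactly recoverable."""
    return SweepParams(
        n_steps=7,
        step_displacement=1.5,
        optimal_step=4,
        noise_sd=0.0,
        drift_amplitude=0.0,
        duration=20.0,
        sample_rate=FS,
    )


@pytest.fixture(scope="session")
def clean_recording(beat_params, clean_sweep):
    rec, truth = generate_recording(beat_params, clean_sweep, seed=42)
    return rec, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Reference-cohort draw (341 normotensive / 52 hypertensive)."""
    return generate_cohort_features(CohortSpec(), seed=11)


def beat_train_signal(
    n_beats: int = 10,
    heart_rate: float = 75.0,
    amplitude: float = 3.0,
    fs: float = FS,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Tile a clean beat template; optionally add white noise."""
    from pulsefactor.synthetic import generate_beat_template

    params = BeatModelParams(amplitude_scale=amplitude, heart_rate=heart_rate)
    beat = generate_beat_template(params, fs)
    sig = np.tile(beat, n_beats)
    if noise_sd > 0:
        sig = sig + np.random.default_rng(seed).normal(0.0, noise_sd, len(sig))
    return sig, beat
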