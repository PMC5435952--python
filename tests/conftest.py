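import numpy as np
import pytest

from eegfatigue.preprocess import RawRecording
from eegfatigue.synthetic import SynthConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synth_cfg():
    """A reduced cohort that keeps end-to-end tests fast: 3 subjects,
    12 s per session state, otherwise generator defaults."""
    return SynthConfig(n_subjects=3, session_seconds=12.0, rng_seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_synth_cfg):
    return generate_cohort(small_synth_cfg)


@pytest.fixture
def tone_recording():
    """10 s, two-channel recording: 10 Hz unit tone on FP1, 50 Hz unit tone
    on FP2, at the acquisition rate."""
    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    data = np.vstack([np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 50 * t)])
    return RawRecording(subject_id="tone", channels=["FP1", "FP2"], fs=fs,
                        data=data, state="normal")


def tone_amplitude(x: np.ndarray, fs: float, freq: float) -> float:
    """Amplitude of the Fourier component nearest ``freq``."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    k = int(np.argmin(np.abs(freqs - freq)))
    return 2 * np.abs(spec[k]) / len(x)
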