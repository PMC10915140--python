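import numpy as np
import pytest

from smrhythm.recording import TimeSeriesRecording
from smrhythm.synthgen import SignalParams, generate_aperiodic_signal


@pytest.fixture(scope="session")
def aperiodic_recording():
    """One 180 s power-law recording (chi = 1.5) shared across tests."""
    return generate_aperiodic_signal(SignalParams(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_envelope(rng, n):
    """Smooth non-negative envelope-like trace of length n."""
    x = rng.standard_normal(n)
    width = int(rng.integers(1, max(2, n // 20)))
    kernel = np.ones(width) / width
    smooth = np.convolve(x, kernel, mode="same")
    return np.abs(smooth) + rng.uniform(0.0, 0.2)


@pytest.fixture()
def make_envelope(rng):
    def _make(n, fs=100.0):
        return TimeSeriesRecording(samples=random_envelope(rng, n), fs=fs)

    return _make
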