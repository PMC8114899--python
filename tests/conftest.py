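import numpy as np
import pytest

from qeeg.io_formats import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_recording():
    """10-s, 2-channel recording at 2000 Hz: 1 Hz / 100 μV sine + noise."""
    fs = 2000
    t = np.arange(0, 10, 1 / fs)
    sig = {
        "ctx_L": 100.0 * np.sin(2 * np.pi * 1.0 * t),
        "hpc": np.random.default_rng(0).normal(0.0, 50.0, len(t)),
    }
    return Recording(signals=sig, fs=fs)


def make_noise(fs=1000.0, duration_s=60.0, rms=50.0, band=(1.0, 50.0), seed=0):
    """Band-limited Gaussian noise with a given RMS, for filter/artifact tests."""
    from scipy import signal as sps

    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, np.random.default_rng(seed).standard_normal(
        int(duration_s * fs)))
    return x * rms / x.std()
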