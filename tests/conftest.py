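import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from icgemd.signal_io import Signal, savgol_smooth
from icgemd.synthetic import SyntheticSpec, noise_sd_for_snr, synth_signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_tone():
    """sin(2*pi*10 t) + sin(2*pi*1 t) at 250 Hz over 20 s, with the tones."""
    fs = 250.0
    t = np.arange(int(20 * fs)) / fs
    tone10 = np.sin(2 * np.pi * 10 * t)
    tone1 = np.sin(2 * np.pi * 1 * t)
    return tone10 + tone1, tone10, tone1, fs


@pytest.fixture(scope="session")
def synthetic_20db():
    """30 s of smoothed synthetic ICG at 20 dB SNR plus its ground truth."""
    spec = SyntheticSpec(duration_s=30.0, seed=7)
    spec = SyntheticSpec(
        **{**spec.__dict__, "noise_sd": noise_sd_for_snr(spec, 20.0)}
    )
    signal, truth = synth_signal(spec)
    return savgol_smooth(signal), truth


@pytest.fixture
def csv_signal(tmp_path):
    """Write a small CSV signal file and return its path."""

    def _write(values, column="icg"):
        path = tmp_path / "signal.csv"
        path.write_text(column + "\n" + "\n".join(str(v) for v in values) + "\n")
        return str(path)

    return _write


def interior_corr(a, b, fraction=0.8):
    """Pearson correlation over the central fraction of two series."""
    n = len(a)
    lo = int(n * (1 - fraction) / 2)
    return float(np.corrcoef(a[lo : n - lo], b[lo : n - lo])[0, 1])
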