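import numpy as np
import pytest

from emgforce.signals import SignalTrace
from emgforce.synthetic import DatasetConfig, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smooth_input(rng):
    """A slowly varying excitation in [0, 1], 1500 samples at 100 Hz."""
    from scipy.signal import butter, sosfiltfilt

    x = sosfiltfilt(butter(2, 5, fs=100.0, output="sos"), rng.uniform(0, 1, 1500))
    x = (x - x.min()) / (x.max() - x.min())
    return SignalTrace(x, fs=100.0, label="u", kind="normalised")


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced-scale synthetic dataset for fast pipeline tests (200 Hz,
    one fifth of the standard trial durations)."""
    cfg = DatasetConfig(fs=200.0, duration_scale=0.2)
    return gen_dataset(cfg, seed=7)
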