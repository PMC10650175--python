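import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from tepnet.containers import EpochsArray


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs(rng):
    """White-noise epochs: 8 trials x 3 channels, -100..+200 ms at 500 Hz."""
    times = np.arange(-50, 101) * 2.0
    data = rng.standard_normal((8, 3, times.size))
    return EpochsArray(data=data, srate=500.0, times=times,
                       labels=["O1", "Oz", "O2"], stim_site="O1")


def make_epochs(data, srate=500.0, t0_index=None, labels=None, stim="none"):
    """Helper to wrap an array as EpochsArray with a ms axis."""
    data = np.asarray(data, float)
    n = data.shape[2]
    if t0_index is None:
        t0_index = n // 2
    times = (np.arange(n) - t0_index) * 1000.0 / srate
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[1])]
    return EpochsArray(data=data, srate=srate, times=times, labels=labels,
                       stim_site=stim)
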