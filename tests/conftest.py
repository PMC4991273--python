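import numpy as np
import pytest

from photophys.decay import MultiExpParams, TimeAxis
from photophys.simulate import SimConfig, gen_decay, gen_irf


@pytest.fixture(scope="session")
def cfg():
    """Standard acquisition conditions: 55 ps channels, 200 ps IRF, 1e4 peak counts."""
    return SimConfig(seed=0, n_channels=1024)


@pytest.fixture(scope="session")
def irf(cfg):
    return gen_irf(cfg)


@pytest.fixture(scope="session")
def mono_trace(cfg, irf):
    """Long-lifetime mono-exponential decay (propyl-dye-like, 15.8 ns)."""
    return gen_decay(MultiExpParams(tau=(15.8,)), irf, cfg, label="mono")


@pytest.fixture
def axis():
    return TimeAxis(t0=0.0, dt=0.055, n=1024)


def direct_convolution(kernel: np.ndarray, signal: np.ndarray) -> np.ndarray:
    """O(n^2) causal convolution oracle, independent of the FFT path."""
    n = len(signal)
    out = np.zeros(n)
    for i in range(n):
        for j in range(i + 1):
            out[i] += kernel[j] * signal[i - j]
    return out
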