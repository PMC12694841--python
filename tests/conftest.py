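import numpy as np
import pytest

from veogblink.signal_io import BipolarVEOG


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_pulse_trace(
    peaks: list[tuple[float, float]],
    fs: float = 500.0,
    duration: float = 10.0,
    width_s: float = 0.2,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> BipolarVEOG:
    """Sum of half-cosine pulses (time, amplitude) on a zero baseline."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for t0, amp in peaks:
        m = np.abs(t - t0) <= width_s / 2
        x[m] += amp * 0.5 * (1 + np.cos(2 * np.pi * (t[m] - t0) / width_s))
    if noise_sigma:
        x += np.random.default_rng(seed).normal(0, noise_sigma, n)
    return BipolarVEOG(x, fs)


@pytest.fixture
def pulse_trace_factory():
    return make_pulse_trace
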