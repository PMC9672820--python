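import numpy as np
import pytest


def tone(f: float, fs: float, n: int, amp: float = 1.0, phase: float = 0.0) -> np.ndarray:
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * f * t + phase)


def interior(x: np.ndarray, frac: float = 0.8) -> np.ndarray:
    cut = int(round(len(x) * (1 - frac) / 2))
    return x[cut : len(x) - cut]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
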