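"""Hilbert spectral analysis: analytic signal, instantaneous amplitude and
frequency.

The analytic signal of a real sequence is built in the discrete Fourier
domain (negative-frequency bins zeroed, positive bins doubled, DC and
Nyquist kept), so its real part equals the input exactly. Its modulus is
the instantaneous amplitude ``a(i)``; the derivative of its unwrapped
phase, scaled by ``fs / 2*pi``, is the instantaneous frequency ``f(i)`` in
Hz. Phase is differentiated with central differences in the interior and
one-sided differences at the ends.

Conventions: samples with zero amplitude get frequency 0 (the phase is
undefined there); negative instantaneous frequencies can occur at
low-amplitude samples and are kept in the trace — consumers that need
nonnegative frequencies (the masking-frequency estimator) clamp them.

Boundary effects (Gibbs ringing of the finite-length transform) mean all
closed-form tolerances in the tests are checked on the *interior* — the
central 80% of samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .exceptions import TooShortSignalError

__all__ = ["AnalyticTrace", "analytic_signal", "inst_amp_freq", "interior_slice"]

MIN_HSA_LEN = 8


@dataclass
class AnalyticTrace:
    """Per-sample instantaneous amplitude (>= 0) and frequency in Hz."""

    amplitude: np.ndarray
    frequency: np.ndarray
    source_fs: float

    def __len__(self) -> int:
        return self.amplitude.size


def analytic_signal(x) -> np.ndarray:
    """Complex analytic signal of ``x`` via the DFT construction."""
    x = np.asarray(x, dtype=float)
    if x.size < MIN_HSA_LEN:
        raise TooShortSignalError(f"need >= {MIN_HSA_LEN} samples, got {x.size}")
    return hilbert(x)


def inst_amp_freq(x, fs: float) -> AnalyticTrace:
    """Instantaneous amplitude and frequency of ``x`` sampled at ``fs`` Hz."""
    z = analytic_signal(x)
    amp = np.abs(z)
    if np.all(amp == 0):
        freq = np.zeros_like(amp)
    else:
        phase = np.unwrap(np.angle(z))
        freq = np.gradient(phase) * fs / (2.0 * np.pi)
        freq = np.where(amp == 0, 0.0, freq)
    return AnalyticTrace(amplitude=amp, frequency=freq, source_fs=float(fs))


def interior_slice(n: int, frac: float = 0.8) -> slice:
    """Slice selecting the central ``frac`` of ``n`` samples."""
    cut = int(round(n * (1.0 - frac) / 2.0))
    return slice(cut, n - cut)
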