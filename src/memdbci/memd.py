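"""Masking empirical mode decomposition (masking EMD).

Plain EMD suffers from *mode mixing*: an intermittent high-frequency
oscillation and a continuous low-frequency one can end up interleaved in a
single IMF. Masking EMD mitigates this by adding a sinusoidal masking
signal ``z(n)`` whose frequency sits at the fast component's scale: the
mask forces the sifting to lock onto that scale everywhere, and averaging
the decompositions of ``x + z`` and ``x - z`` cancels the mask itself:

1. extract IMF1 of ``x`` by plain EMD and Hilbert-analyse it, giving
   per-sample amplitude ``a(i)`` and frequency ``f(i)``;
2. mask amplitude  ``a_z = (1.6 / N) * sum_i a(i)``;
3. mask frequency  ``f_z = sum_i a(i) f(i)^2 / sum_i a(i) f(i)``
   (the amplitude-weighted mean instantaneous frequency — negative
   frequency samples are clamped to zero in the weights);
4. ``z(n) = a_z * sin(2*pi*f_z*n/fs + phase)``, phase 0 by default;
5. ``y+`` = IMF1 of ``x + z``, ``y-`` = IMF1 of ``x - z``,
   and the masked IMF is ``y = (y+ + y-) / 2``.

With ``a_z = 0`` the procedure reduces exactly to plain EMD. The full
decomposition applies the masked extraction recursively to successive
residues, re-estimating the mask at every level (switchable to
first-level-only); completeness is preserved because the residue absorbs
whatever the IMFs do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .emd import (
    MIN_DECOMPOSE_LEN,
    IMFSet,
    Signal,
    SiftStop,
    _decomposable,
    extract_imf,
)
from .exceptions import InsufficientExtremaError, TooShortSignalError
from .hsa import AnalyticTrace, inst_amp_freq

__all__ = [
    "MaskSpec",
    "MASK_AMPLITUDE_COEF",
    "masking_params",
    "build_mask",
    "memd_extract_imf",
    "memd_decompose",
]

logger = logging.getLogger(__name__)

# coefficient of the mask-amplitude estimate; fixed by the method
MASK_AMPLITUDE_COEF = 1.6


@dataclass
class MaskSpec:
    """A rendered masking sinusoid and the parameters that produced it."""

    a_z: float
    f_z: float
    phase: float
    z: np.ndarray

    @property
    def is_zero(self) -> bool:
        return self.a_z == 0.0 or not np.any(self.z)


def masking_params(trace: AnalyticTrace) -> tuple[float, float]:
    """Mask amplitude and frequency from an IMF's Hilbert trace.

    ``a_z`` is 1.6 times the mean instantaneous amplitude; ``f_z`` is the
    amplitude-weighted mean instantaneous frequency
    ``sum(a f^2) / sum(a f)``. Negative frequencies (phase-slip artefacts
    at low-amplitude samples) are clamped to zero in the weighting. An
    all-zero amplitude trace yields ``(0, 0)`` — the zero-mask fallback
    that degrades masking EMD to plain EMD.
    """
    a = np.asarray(trace.amplitude, dtype=float)
    if a.size == 0:
        raise ValueError("empty analytic trace")
    f = np.clip(np.asarray(trace.frequency, dtype=float), 0.0, None)
    if not np.any(a > 0):
        return 0.0, 0.0
    a_z = MASK_AMPLITUDE_COEF * float(np.mean(a))
    den = float(np.sum(a * f))
    f_z = float(np.sum(a * f**2)) / den if den > 0 else 0.0
    return a_z, f_z


def build_mask(a_z: float, f_z: float, n: int, fs: float, phase: float = 0.0) -> MaskSpec:
    """Render the masking sinusoid ``a_z * sin(2*pi*f_z*t + phase)``.

    A mask frequency at or above Nyquist is clamped to ``0.45 * fs`` with a
    logged warning (it cannot be represented, and the estimate that
    produced it is unreliable anyway).
    """
    if f_z >= fs / 2:
        logger.warning(
            "mask frequency %.3f Hz >= Nyquist (fs=%.1f); clamping to 0.45*fs",
            f_z,
            fs,
        )
        f_z = 0.45 * fs
    t = np.arange(n) / fs
    z = a_z * np.sin(2.0 * np.pi * f_z * t + phase)
    return MaskSpec(a_z=float(a_z), f_z=float(f_z), phase=float(phase), z=z)


def memd_extract_imf(
    x: Signal, stop: SiftStop | None = None, phase: float = 0.0
) -> tuple[np.ndarray, MaskSpec]:
    """Extract one masked IMF from ``x``.

    Runs the full mask pipeline (plain IMF1 -> Hilbert trace -> mask
    parameters -> +/- decomposition -> average). If sifting of the masked
    sums fails for lack of extrema, falls back to the plain IMF with a
    logged notice.
    """
    if stop is None:
        stop = SiftStop()
    samples = x.samples
    imf1, _ = extract_imf(samples, stop)
    trace = inst_amp_freq(imf1, x.fs)
    a_z, f_z = masking_params(trace)
    mask = build_mask(a_z, f_z, samples.size, x.fs, phase)
    if mask.is_zero:
        return imf1, mask
    try:
        y_plus, _ = extract_imf(samples + mask.z, stop)
        y_minus, _ = extract_imf(samples - mask.z, stop)
    except InsufficientExtremaError:
        logger.info("masked sift lost extrema; falling back to plain IMF")
        return imf1, MaskSpec(a_z=0.0, f_z=0.0, phase=phase, z=np.zeros_like(samples))
    return 0.5 * (y_plus + y_minus), mask


def memd_decompose(
    x: Signal,
    max_imfs: int = 10,
    stop: SiftStop | None = None,
    *,
    mask_levels: str = "all",
    phase: float = 0.0,
) -> IMFSet:
    """Full masking-EMD decomposition of one signal.

    ``mask_levels="all"`` (default) re-estimates the mask from the current
    residue's IMF1 at every level; ``"first"`` masks only the first level
    and decomposes the rest by plain sifting.
    """
    if stop is None:
        stop = SiftStop()
    samples = x.samples
    if samples.size < MIN_DECOMPOSE_LEN:
        raise TooShortSignalError(
            f"need >= {MIN_DECOMPOSE_LEN} samples, got {samples.size}"
        )
    residue = samples.copy()
    imfs: list[np.ndarray] = []
    masks: list[MaskSpec] = []
    while len(imfs) < max_imfs and _decomposable(residue):
        if mask_levels == "all" or (mask_levels == "first" and not imfs):
            imf, mask = memd_extract_imf(Signal(residue, x.fs), stop, phase)
        else:
            imf, _ = extract_imf(residue, stop)
            mask = MaskSpec(a_z=0.0, f_z=0.0, phase=phase, z=np.zeros_like(residue))
        imfs.append(imf)
        masks.append(mask)
        residue = residue - imf
    return IMFSet(imfs=imfs, residue=residue, sift_counts=[], masks=masks)
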