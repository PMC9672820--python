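"""Classical empirical mode decomposition (EMD).

EMD splits a signal into intrinsic mode functions (IMFs) — locally
band-limited AM-FM components — by iteratively *sifting*: subtracting the
mean of the upper and lower extrema envelopes until the local mean is near
zero. Successive IMFs are extracted from the running residue until it is
monotone (fewer than two maxima or minima).

Implementation choices (the procedure itself does not fix them):

* envelopes are natural cubic splines through the extrema, with the two
  extrema nearest each end mirrored about the signal boundary to tame
  end swings;
* plateaus of equal samples contribute a single extremum at their
  midpoint index (floor for even-length plateaus);
* sifting stops on the Cauchy criterion
  ``SD = sum((h_prev - h_new)^2) / sum(h_prev^2) < sd_tol``
  (default 0.2) or after ``max_sifts`` iterations (default 100).

Whatever the stopping parameters, the decomposition is *complete* by
construction: the IMFs plus the final residue telescope back to the input
exactly (up to floating-point rounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import InsufficientExtremaError, TooShortSignalError

__all__ = [
    "Signal",
    "SiftStop",
    "IMFSet",
    "find_extrema",
    "envelopes",
    "sift_once",
    "extract_imf",
    "emd_decompose",
]

MIN_DECOMPOSE_LEN = 16


@dataclass(frozen=True)
class Signal:
    """One channel's samples with its sampling rate in Hz."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class SiftStop:
    """Sifting stop rule: Cauchy SD tolerance and an iteration cap."""

    sd_tol: float = 0.2
    max_sifts: int = 100


@dataclass
class IMFSet:
    """Ordered IMFs plus the final residue of one signal.

    ``sum(imfs) + residue`` reconstructs the source exactly (telescoping).
    ``masks`` is filled by the masking-EMD variant and is None for plain EMD.
    """

    imfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int] = field(default_factory=list)
    masks: list | None = None

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def find_extrema(x) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of ``x``.

    A run of equal samples (plateau) bounded by lower (resp. higher)
    neighbours yields a single maximum (resp. minimum) at the plateau's
    midpoint index, floored for even plateaus. Endpoints are never extrema.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)

    # compress plateaus: keep first sample of each run of equal values
    keep = np.concatenate(([True], np.diff(x) != 0))
    starts = np.flatnonzero(keep)
    xc = x[starts]
    ends = np.concatenate((starts[1:] - 1, [x.size - 1]))

    if xc.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)

    d = np.sign(np.diff(xc))
    # interior run j is a max if rising into it and falling out (and vice versa)
    j = np.arange(1, xc.size - 1)
    is_max = (d[:-1] > 0) & (d[1:] < 0)
    is_min = (d[:-1] < 0) & (d[1:] > 0)
    mid = (starts[j] + ends[j]) // 2
    return mid[is_max], mid[is_min]


def _mirrored_points(idx: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extend extrema (idx, x[idx]) past both signal ends by mirroring.

    The two extrema nearest each end are reflected about the boundary
    sample so the spline is anchored outside the observed range.
    """
    n = x.size
    pts = {int(i): x[i] for i in idx}
    for i in idx[:2]:
        m = -int(i)
        if m < int(idx[0]):
            pts[m] = x[i]
    for i in idx[-2:]:
        m = 2 * (n - 1) - int(i)
        if m > int(idx[-1]):
            pts[m] = x[i]
    keys = np.array(sorted(pts))
    vals = np.array([pts[k] for k in keys])
    return keys, vals


def envelopes(x, maxima, minima) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower extrema envelopes of ``x``.

    Natural cubic splines through the maxima (resp. minima), boundary
    handled by mirroring (see module docstring). Spline overshoot means
    ``upper >= lower`` is *not* guaranteed pointwise and is not asserted.

    Raises
    ------
    InsufficientExtremaError
        Fewer than 2 maxima or 2 minima — the caller stops sifting.
    """
    x = np.asarray(x, dtype=float)
    maxima = np.asarray(maxima, dtype=int)
    minima = np.asarray(minima, dtype=int)
    if maxima.size < 2 or minima.size < 2:
        raise InsufficientExtremaError(
            f"need >= 2 extrema on each side, got {maxima.size} maxima / "
            f"{minima.size} minima"
        )
    t = np.arange(x.size)
    up_i, up_v = _mirrored_points(maxima, x)
    lo_i, lo_v = _mirrored_points(minima, x)
    upper = CubicSpline(up_i, up_v, bc_type="natural")(t)
    lower = CubicSpline(lo_i, lo_v, bc_type="natural")(t)
    return upper, lower


def sift_once(x) -> np.ndarray:
    """One sifting step: subtract the mean of the two envelopes."""
    x = np.asarray(x, dtype=float)
    maxima, minima = find_extrema(x)
    upper, lower = envelopes(x, maxima, minima)
    return x - 0.5 * (upper + lower)


def extract_imf(x, stop: SiftStop | None = None) -> tuple[np.ndarray, int]:
    """Sift ``x`` until the Cauchy SD criterion or the iteration cap.

    Returns the IMF candidate and the number of sifts performed.
    ``max_sifts = 0`` returns the input unchanged.
    """
    if stop is None:
        stop = SiftStop()
    h = np.asarray(x, dtype=float).copy()
    n_sifts = 0
    for _ in range(stop.max_sifts):
        h_new = sift_once(h)
        n_sifts += 1
        denom = float(np.sum(h**2))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < stop.sd_tol:
            break
    return h, n_sifts


def _decomposable(x: np.ndarray) -> bool:
    maxima, minima = find_extrema(x)
    return maxima.size >= 2 and minima.size >= 2


def emd_decompose(
    sig: Signal, max_imfs: int = 10, stop: SiftStop | None = None
) -> IMFSet:
    """Full EMD of one signal.

    IMFs are extracted from the running residue until it has fewer than two
    maxima or two minima, or ``max_imfs`` is reached. The residue absorbs
    everything not captured, so reconstruction is exact.
    """
    if stop is None:
        stop = SiftStop()
    x = sig.samples
    if x.size < MIN_DECOMPOSE_LEN:
        raise TooShortSignalError(
            f"need >= {MIN_DECOMPOSE_LEN} samples, got {x.size}"
        )
    residue = x.copy()
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    while len(imfs) < max_imfs and _decomposable(residue):
        imf, ns = extract_imf(residue, stop)
        imfs.append(imf)
        counts.append(ns)
        residue = residue - imf
    return IMFSet(imfs=imfs, residue=residue, sift_counts=counts)
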