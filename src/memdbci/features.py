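"""Feature families for motor-imagery EEG: energy, morphological measures,
fuzzy approximate entropy, and autoregressive coefficients.

Features are computed per IMF of each channel's decomposition (masking EMD
by default), then concatenated into one fixed-layout vector per trial. Per
IMF the layout is::

    energy | AA PA NA TT TAA | FAP | a1 .. ap

* energy: sum of squared samples.
* morphological: AA = max |x| (peak absolute amplitude), PA / NA = the
  positive / negative parts of the sum, TT = PA + NA (the plain sum),
  TAA = PA + |NA| (the absolute sum). TT and TAA are exact algebraic
  identities of PA and NA.
* FAP: fuzzy approximate entropy — the regularity statistic obtained by
  replacing approximate entropy's hard similarity threshold with an
  exponential fuzzy membership of template distances.
* AR: order-7 autoregressive coefficients fitted by Burg's method in the
  convention ``X(t) = sum_i a(i) X(t-i) + e(t)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist
from statsmodels.regression.linear_model import burg

from .emd import Signal, SiftStop, emd_decompose
from .exceptions import InvalidSpecError, MemdBciError, TooShortSignalError
from .memd import memd_decompose

__all__ = [
    "FuzzyEnParams",
    "ARModel",
    "Morphology",
    "FeatureConfig",
    "FeatureVector",
    "energy",
    "morphological",
    "fuzzy_approx_entropy",
    "ar_coefficients",
    "extract_features",
]

logger = logging.getLogger(__name__)


def energy(h) -> float:
    """Sum of squared samples."""
    h = np.asarray(h, dtype=float)
    if h.size == 0:
        raise InvalidSpecError("energy of an empty sequence")
    return float(np.sum(h**2))


class Morphology(NamedTuple):
    AA: float  # peak absolute amplitude, max |x|
    PA: float  # positive part of the sum
    NA: float  # negative part of the sum (<= 0)
    TT: float  # PA + NA == sum(x)
    TAA: float  # PA + |NA| == sum(|x|)


def morphological(x, *, aa_as_area: bool = False) -> Morphology:
    """Morphological features of a sequence.

    ``AA`` defaults to the peak absolute amplitude ``max |x|``; with
    ``aa_as_area=True`` it becomes the absolute area ``sum |x|`` instead
    (the name suggests an area; both readings are offered, peak is the
    default).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidSpecError("morphological features of an empty sequence")
    ax = np.abs(x)
    aa = float(np.sum(ax)) if aa_as_area else float(np.max(ax))
    pa = float(np.sum(0.5 * (x + ax)))
    na = float(np.sum(0.5 * (x - ax)))
    return Morphology(AA=aa, PA=pa, NA=na, TT=pa + na, TAA=pa + abs(na))


@dataclass
class FuzzyEnParams:
    """Fuzzy-approximate-entropy parameters.

    ``m`` is the template (embedding) length; ``r`` the tolerance — with
    ``relative_r`` (default) it is a fraction of the signal's standard
    deviation, otherwise in signal units; ``n_grad`` the exponent of the
    fuzzy membership gradient ``exp(-d^n / r)``.
    """

    m: int = 2
    r: float = 0.2
    n_grad: float = 2.0
    relative_r: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise InvalidSpecError("m must be >= 1")
        if self.r <= 0:
            raise InvalidSpecError("r must be > 0")
        if self.n_grad <= 0:
            raise InvalidSpecError("n_grad must be > 0")


def _phi(x: np.ndarray, m: int, r: float, n_grad: float) -> float:
    """Mean log similarity degree over all length-``m`` templates.

    Templates are the sliding windows of length ``m`` with their own mean
    removed; distances are Chebyshev (max component); the similarity of a
    pair is the fuzzy membership ``exp(-d^n / r)``; each template's degree
    is its mean similarity to all *other* templates.
    """
    W = sliding_window_view(x, m).astype(float)
    Xc = W - W.mean(axis=1, keepdims=True)
    d = cdist(Xc, Xc, metric="chebyshev")
    D = np.exp(-(d**n_grad) / r)
    M = W.shape[0]
    phi_i = (D.sum(axis=1) - 1.0) / (M - 1)  # exclude the self pair D_ii = 1
    return float(np.mean(np.log(phi_i)))


def fuzzy_approx_entropy(x, params: FuzzyEnParams | None = None) -> float:
    """Fuzzy approximate entropy ``FAP = Phi^m - Phi^{m+1}``.

    Low values mean high regularity (a constant signal gives exactly 0);
    broadband noise scores higher than a tone of the same variance.
    """
    if params is None:
        params = FuzzyEnParams()
    x = np.asarray(x, dtype=float)
    if x.size <= params.m + 1:
        raise TooShortSignalError(
            f"need more than m+1={params.m + 1} samples, got {x.size}"
        )
    r = params.r * float(np.std(x)) if params.relative_r else params.r
    if r == 0.0:
        # constant signal: all template distances are zero, every membership
        # is 1 and both Phi terms vanish regardless of r
        return 0.0
    return _phi(x, params.m, r, params.n_grad) - _phi(x, params.m + 1, r, params.n_grad)


@dataclass
class ARModel:
    """Autoregressive model ``X(t) = sum_i coeffs[i-1] * X(t-i) + e(t)``."""

    order: int
    coeffs: np.ndarray
    noise_variance: float


def ar_coefficients(x, p: int = 7) -> ARModel:
    """Fit an AR(p) model by Burg's method (order 7 by default).

    Burg estimation is the standard choice for short EEG segments: it is
    stable and needs no windowing. The mean is removed before fitting.
    """
    x = np.asarray(x, dtype=float)
    if p < 1:
        raise InvalidSpecError("order must be >= 1")
    if x.size <= 2 * p:
        raise TooShortSignalError(f"need more than 2p={2 * p} samples, got {x.size}")
    if np.max(x) == np.min(x):
        raise InvalidSpecError("cannot fit AR model to a constant signal")
    coeffs, sigma2 = burg(x, order=p, demean=True)
    return ARModel(order=p, coeffs=np.asarray(coeffs), noise_variance=float(sigma2))


@dataclass
class FeatureConfig:
    """What to compute per trial: decomposition method, IMFs kept, and the
    per-family parameters."""

    method: str = "memd"  # "memd" | "emd" | "raw" (features on raw channels)
    n_imfs: int = 3
    fuzzy: FuzzyEnParams = field(default_factory=FuzzyEnParams)
    ar_order: int = 7
    aa_as_area: bool = False
    stop: SiftStop = field(default_factory=SiftStop)

    @property
    def n_per_imf(self) -> int:
        return 1 + 5 + 1 + self.ar_order


@dataclass
class FeatureVector:
    """Concatenated features of one trial with stable, named layout."""

    values: np.ndarray
    names: list[str]

    def __len__(self) -> int:
        return self.values.size


def _imf_features(h: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    out = np.zeros(cfg.n_per_imf)
    out[0] = energy(h)
    out[1:6] = morphological(h, aa_as_area=cfg.aa_as_area)
    try:
        out[6] = fuzzy_approx_entropy(h, cfg.fuzzy)
    except MemdBciError:
        out[6] = 0.0
    try:
        out[7:] = ar_coefficients(h, cfg.ar_order).coeffs
    except MemdBciError:
        out[7:] = 0.0
    return out


def feature_names(n_channels: int, cfg: FeatureConfig) -> list[str]:
    """Column names matching :func:`extract_features` order."""
    fam = (
        ["energy", "AA", "PA", "NA", "TT", "TAA", "FAP"]
        + [f"ar{i}" for i in range(1, cfg.ar_order + 1)]
    )
    return [
        f"ch{c}_imf{k}_{name}"
        for c in range(n_channels)
        for k in range(1, cfg.n_imfs + 1)
        for name in fam
    ]


def extract_features(trial: np.ndarray, fs: float, cfg: FeatureConfig | None = None) -> FeatureVector:
    """All four feature families for one channels x samples trial.

    Each channel is decomposed (masking EMD by default) and the first
    ``n_imfs`` IMFs are featurized; missing IMFs (shallow decompositions)
    leave their slots zero. A channel whose decomposition fails is
    zero-filled with a logged warning rather than aborting the trial.
    """
    if cfg is None:
        cfg = FeatureConfig()
    trial = np.atleast_2d(np.asarray(trial, dtype=float))
    n_channels = trial.shape[0]
    per_ch = cfg.n_imfs * cfg.n_per_imf
    values = np.zeros(n_channels * per_ch)
    for c in range(n_channels):
        sig = Signal(trial[c], fs)
        try:
            if cfg.method == "raw":
                comps = [trial[c]] * 1
            elif cfg.method == "emd":
                comps = emd_decompose(sig, max_imfs=cfg.n_imfs, stop=cfg.stop).imfs
            else:
                comps = memd_decompose(sig, max_imfs=cfg.n_imfs, stop=cfg.stop).imfs
        except MemdBciError as exc:
            logger.warning("decomposition failed on channel %d (%s); zero-filling", c, exc)
            continue
        for k, h in enumerate(comps[: cfg.n_imfs]):
            lo = c * per_ch + k * cfg.n_per_imf
            values[lo : lo + cfg.n_per_imf] = _imf_features(h, cfg)
    return FeatureVector(values=values, names=feature_names(n_channels, cfg))
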