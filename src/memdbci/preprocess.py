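"""Min-max normalization of signals into a target range.

EEG amplitudes vary widely between recordings and channels; mapping each
channel onto a fixed range ``[y_min, y_max]`` (default ``[-1, +1]``) puts
every trial on a common scale before decomposition and classification:

    z_i = (y_max - y_min) * (x_i - x_min) / (x_max - x_min) + y_min

The map is affine and order preserving, so waveform shape is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateRangeError, InvalidSpecError

__all__ = ["NormalizationSpec", "minmax_normalize", "normalize_trial"]


@dataclass
class NormalizationSpec:
    """Target range plus the observed input extremes (recorded for audit).

    ``x_min`` / ``x_max`` are filled in by :func:`minmax_normalize` and let a
    caller invert the map or apply the same map to held-out data.
    """

    y_min: float = -1.0
    y_max: float = 1.0
    x_min: float | None = None
    x_max: float | None = None

    def __post_init__(self) -> None:
        if not self.y_max > self.y_min:
            raise InvalidSpecError(
                f"y_max ({self.y_max}) must exceed y_min ({self.y_min})"
            )


def minmax_normalize(
    x,
    spec: NormalizationSpec | None = None,
    *,
    on_constant: str = "raise",
) -> np.ndarray:
    """Affinely map ``x`` onto ``[spec.y_min, spec.y_max]``.

    Parameters
    ----------
    x
        Real sequence with at least 2 samples.
    spec
        Target range; defaults to ``[-1, +1]``. Its ``x_min``/``x_max``
        fields are updated in place with the observed extremes.
    on_constant
        ``"raise"`` (default) raises :class:`DegenerateRangeError` on a
        constant input; ``"zeros"`` returns an all-zero array instead.

    Returns
    -------
    numpy.ndarray
        Same length as ``x``; min equals ``y_min`` and max equals ``y_max``
        to machine precision for non-constant input.
    """
    if spec is None:
        spec = NormalizationSpec()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InvalidSpecError("minmax_normalize expects a 1-D sequence")
    if x.size < 2:
        raise InvalidSpecError("need at least 2 samples to normalize")

    x_min = float(np.min(x))
    x_max = float(np.max(x))
    spec.x_min, spec.x_max = x_min, x_max
    if x_max == x_min:
        if on_constant == "zeros":
            return np.zeros_like(x)
        raise DegenerateRangeError(
            "constant input has zero dynamic range; "
            "pass on_constant='zeros' for the documented fallback"
        )
    return (spec.y_max - spec.y_min) * (x - x_min) / (x_max - x_min) + spec.y_min


def normalize_trial(trial: np.ndarray, *, y_min: float = -1.0, y_max: float = 1.0) -> np.ndarray:
    """Normalize each channel (row) of a channels x samples trial independently.

    Constant channels map to all zeros (documented fallback) so a flat
    reference channel cannot abort a whole trial.
    """
    trial = np.asarray(trial, dtype=float)
    out = np.empty_like(trial)
    for c in range(trial.shape[0]):
        out[c] = minmax_normalize(
            trial[c], NormalizationSpec(y_min=y_min, y_max=y_max), on_constant="zeros"
        )
    return out
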