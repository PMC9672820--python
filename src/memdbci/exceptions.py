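"""Exception hierarchy for memdbci.

All library errors derive from :class:`MemdBciError` so callers can catch
one base class at pipeline boundaries.
"""


class MemdBciError(Exception):
    """Base class for all memdbci errors."""


class InvalidSpecError(MemdBciError, ValueError):
    """A component / configuration specification violates its invariants."""


class TooShortSignalError(MemdBciError, ValueError):
    """Signal has too few samples for the requested operation."""


class DegenerateRangeError(MemdBciError, ValueError):
    """Min-max normalization of a constant signal (zero dynamic range)."""


class InsufficientExtremaError(MemdBciError, ValueError):
    """Fewer than two maxima or two minima: sifting cannot proceed."""


class DivergenceError(MemdBciError, RuntimeError):
    """Network training produced non-finite values."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(
            f"training diverged (non-finite values) at epoch {epoch}; "
            "try a smaller learning rate"
        )
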