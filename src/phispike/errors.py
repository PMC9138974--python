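"""Exception types shared across the package."""


class PhiSpikeError(Exception):
    """Base class for all package errors."""


class RankDeficientError(PhiSpikeError):
    """A covariance (sub)matrix is numerically singular.

    Raised when a determinant is non-positive or the condition number
    exceeds the rank tolerance; callers such as the robust-removal loop
    catch this to drop low-variance neurons and retry.
    """


class DegenerateSystemError(PhiSpikeError):
    """Fewer than two usable neurons remain; Phi is undefined."""


class InputFormatError(PhiSpikeError):
    """Malformed input table (carries the offending line where known)."""
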