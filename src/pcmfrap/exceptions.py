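"""Typed errors raised across the package."""


class PcmFrapError(Exception):
    """Base class for all package errors."""


class NoSignalError(PcmFrapError):
    """No pixel rises above the detection threshold."""


class NormalizationError(PcmFrapError):
    """A profile cannot be normalized (non-positive peak, or flag misuse)."""


class UnboundedWidthError(PcmFrapError):
    """A profile never falls below half of its peak within the measured grid."""


class GridMismatchError(PcmFrapError):
    """Profiles defined on incompatible ring grids were combined."""


class DegenerateVarianceError(PcmFrapError):
    """Paired differences are identical to machine precision: the t test is
    undefined, but the effect size is still available on the error object."""

    def __init__(self, message: str, percent_reduction: float):
        super().__init__(message)
        self.percent_reduction = percent_reduction


class ConfigError(PcmFrapError):
    """Malformed or incomplete run configuration."""
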