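"""Exception hierarchy.

Every error raised by the package derives from :class:`GptkError` so callers
(and the CLI exit-code mapping) can distinguish configuration problems, data
problems and numerical failures.
"""


class GptkError(Exception):
    """Base class for all package errors."""


class ConfigError(GptkError):
    """Invalid configuration: bad parameter value, malformed space or grid."""


class DataError(GptkError):
    """Invalid or inconsistent input data."""


class FormatError(DataError):
    """A file is not in the expected on-disk format (magic bytes, truncation)."""


class DimensionError(DataError):
    """Companion files or arrays disagree about dimensions."""


class DuplicateIdError(DataError):
    """Sample or marker identifiers are not unique."""


class UnknownTraitError(DataError):
    """A requested trait column does not exist."""


class EmptyPanelError(DataError):
    """Quality control removed every marker or every individual."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class ShapeError(DataError):
    """Array shapes are incompatible with the fitted state."""


class NumericalError(GptkError):
    """A numerical computation failed (singular system, non-PSD matrix...)."""


class ConvergenceError(NumericalError):
    """An iterative solver hit its iteration cap before reaching tolerance."""

    def __init__(self, message, kkt_violation=None):
        super().__init__(message)
        self.kkt_violation = kkt_violation


class UndefinedStatisticError(NumericalError):
    """A statistic is undefined for the given input (zero variance, all-missing)."""
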