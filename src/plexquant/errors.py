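"""Exception hierarchy for the quantification pipeline.

Every stage raises a subclass of :class:`PlexquantError`, so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class PlexquantError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PlexquantError):
    """A generator or pipeline configuration violates an invariant."""


class SchemaError(PlexquantError):
    """A cell table is missing required columns or contains invalid values."""


class CalibrationError(PlexquantError):
    """Threshold calibration preconditions are not met."""


class InsufficientCellsError(PlexquantError):
    """An operation requires a non-empty (or larger) cell population."""


class UndefinedReferenceError(PlexquantError):
    """The reference population is missing or has zero mean intensity."""


class GeometryError(PlexquantError):
    """Spot or region geometry is degenerate (non-positive diameter/area)."""


class ReportError(PlexquantError):
    """Report generation was asked to render empty input."""
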