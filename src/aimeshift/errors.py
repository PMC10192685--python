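"""Exception hierarchy."""


class AimeshiftError(Exception):
    """Base class for package errors."""


class PlateConfigError(AimeshiftError):
    """Invalid plate/layout/dose configuration or missing table columns."""


class PlateParseError(AimeshiftError):
    """A well table row could not be parsed; message names the rows/cells."""


class LayoutError(AimeshiftError):
    """A well does not belong to any mode band or control position."""


class QCError(AimeshiftError):
    """Quality-control failure (no baseline wells, nonpositive bval, ...)."""


class FittingError(AimeshiftError):
    """Concentration-response fitting failed for a series."""


class FixtureError(AimeshiftError):
    """Packaged printed-results fixture is malformed."""
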