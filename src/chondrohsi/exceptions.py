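"""Exception hierarchy.

Everything raised on purpose derives from :class:`ChondroHSIError` so callers
can catch pipeline failures without swallowing programming errors.
"""


class ChondroHSIError(Exception):
    """Base class for all errors raised by this package."""


class CalibrationError(ChondroHSIError):
    """White/dark reference calibration is impossible (e.g. white <= dark)."""


class GridRangeError(ChondroHSIError, ValueError):
    """A requested wavelength lies outside the cube's wavelength grid."""


class EmptyWindowError(ChondroHSIError, ValueError):
    """A spectral averaging window contains no band centers."""


class InfeasibleTargetError(ChondroHSIError):
    """Spectral index targets cannot be realized as a non-negative spectrum."""


class LayoutError(ChondroHSIError):
    """The requested region layout does not fit the cube's spatial shape."""


class GenerationError(ChondroHSIError):
    """Target sampling produced invalid (non-positive) index values."""


class ConsistencyError(ChondroHSIError):
    """Label maps and annotations disagree (orphan labels or annotations)."""


class GradeOutOfScopeError(ChondroHSIError, ValueError):
    """ICRS grade 2 regions are outside the study's two-class design."""


class InsufficientDataError(ChondroHSIError):
    """Too few complete healthy/damaged pairs for a paired analysis."""


class DegenerateDataError(ChondroHSIError):
    """Paired differences are all zero; no test statistic is defined."""


class FormatError(ChondroHSIError):
    """A file on disk is malformed (ENVI header/binary mismatch, bad CSV...)."""
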