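"""Exception hierarchy for dose-grid and QA-chain failures.

Every error raised by this package derives from :class:`MgdrqaError`, so
callers can catch the package's failures without masking programming errors.
"""


class MgdrqaError(Exception):
    """Base class for all errors raised by mgdrqa."""


class FormatError(MgdrqaError):
    """A file does not conform to the declared dialect (names the attribute)."""


class GeometryError(MgdrqaError):
    """Degenerate or inconsistent spatial geometry (rays, planes, polygons)."""


class CongruenceError(MgdrqaError):
    """Two grids or masks that must share origin/spacing/shape do not."""


class DegenerateInputError(MgdrqaError):
    """Input is structurally valid but empty after filtering (e.g. all nodes
    below threshold, empty structure mask)."""


class OutOfBoundsError(MgdrqaError):
    """A sample point lies outside the grid bounding box."""


class InvalidParameterError(MgdrqaError):
    """A model parameter violates its domain (e.g. EUD exponent a = 0)."""


class UndefinedRateError(MgdrqaError):
    """A passing rate is requested over an empty evaluated set; the rate is
    undefined (neither 0 nor 100)."""
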