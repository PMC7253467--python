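"""Exception hierarchy.

All package errors derive from :class:`FoveametryError` so callers can catch
one base class; subclasses map one-to-one onto the failure modes of the
analysis stages.
"""


class FoveametryError(Exception):
    """Base class for all errors raised by foveametry."""


class ConfigurationError(FoveametryError):
    """Invalid generator or pipeline configuration."""


class InvalidWarpError(FoveametryError):
    """Warp specification does not define a strictly increasing map."""


class SchemaError(FoveametryError):
    """Malformed input file (missing column, bad cell, bad ordering)."""


class FixtureIntegrityError(FoveametryError):
    """Packaged reference table failed its checksum."""


class FitError(FoveametryError):
    """Spline fitting precondition violated (too few points, ...)."""


class EccentricityRangeError(FoveametryError):
    """Requested eccentricity lies outside a curve's domain."""


class UnreachableValueError(FoveametryError):
    """Control cumulative value exceeds the preterm curve's range, so no
    horizontal displacement exists within the integration window."""


class BandNotFoundError(FoveametryError):
    """No interior reflectivity peak (or no usable trough) in the window."""


class DegenerateProfileError(FoveametryError):
    """Reflectivity window is flat; peak/trough structure undefined."""


class SegmentationError(FoveametryError):
    """Half-height boundary could not be placed on a band flank."""


class UndefinedIndexError(FoveametryError):
    """Morphometric ratio has a zero denominator."""
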