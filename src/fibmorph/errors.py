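"""Exception hierarchy.

Every error the package raises deliberately derives from :class:`FibmorphError`
so callers can catch pipeline failures without masking programming errors.
"""


class FibmorphError(Exception):
    """Base class for all fibmorph errors."""


class FormatError(FibmorphError):
    """A file could not be read in any supported volume format."""


class MetadataError(FibmorphError):
    """Required physical metadata (voxel spacing) is missing."""


class SchemaError(FibmorphError):
    """A tabular input does not have the required columns."""


class ValidationError(FibmorphError):
    """Input values violate a documented invariant (e.g. duplicate tile ids)."""


class ConfigurationError(FibmorphError):
    """An unknown method/option identifier or inconsistent parameters."""


class DomainError(FibmorphError):
    """A numeric argument outside the mathematical domain of an operation."""


class InsufficientDataError(FibmorphError):
    """Too few objects/values for the requested statistic."""


class FeasibilityError(FibmorphError):
    """A synthetic-geometry request cannot be satisfied (e.g. packing too dense)."""


class IncompatibilityError(FibmorphError):
    """Two objects that must share a grid/graticule do not."""
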