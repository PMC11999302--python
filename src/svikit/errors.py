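"""Exception hierarchy.

Every stage of the pipeline raises a distinct subclass of :class:`SviError`
so callers (and the CLI, which maps stages to exit-code families) can tell
configuration problems apart from data problems.
"""


class SviError(Exception):
    """Base class for all svikit errors."""


class ConfigurationError(SviError):
    """A hierarchy configuration document is malformed or incomplete."""


class LinkageError(ConfigurationError):
    """An indicator or domain references an id that does not resolve."""


class TableError(SviError):
    """An indicator table violates its contract (ids, shapes, emptiness)."""


class DegenerateColumnError(TableError):
    """A column is constant or has too few observed values to standardize."""


class MissingDataError(TableError):
    """Missing cells encountered under the ``error`` policy."""


class TierRoutingError(SviError):
    """A weighting operation was asked to handle a tier it does not cover."""


class ConsistencyError(SviError):
    """Two artifacts that must describe the same data do not line up."""


class ClassificationError(SviError):
    """A classification scheme cannot be applied to the given scores."""


class ComparisonError(SviError):
    """Too few shared areas (or otherwise unusable inputs) for comparison."""


class GeometryError(SviError):
    """Spatial units are unreadable, invalid or inconsistent."""


class JoinError(GeometryError):
    """Attribute join between scores and geometries found no overlap."""


class UnsupportedFormatError(GeometryError):
    """A spatial file format this build does not read or write."""
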