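"""Exception hierarchy for the footprint pipeline.

Every stage raises a subclass of :class:`FpmError` so callers can catch
pipeline problems without masking programming errors.
"""


class FpmError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(FpmError):
    """A table is missing a declared column or has a malformed header."""


class ReferentialError(FpmError):
    """A code (country, commodity) is used but absent from the registry."""


class ValidationError(FpmError):
    """A value violates a declared constraint (e.g. negative quantity)."""


class ConfigurationError(FpmError):
    """Run configuration or allocation inputs are inconsistent."""


class ParameterError(FpmError):
    """Synthetic-world parameters are infeasible."""


class MappingError(FpmError):
    """A commodity cannot be mapped through the commodity tree."""


class AttributionError(FpmError):
    """Feed-pool attribution is impossible (e.g. all-zero weights)."""


class DataError(FpmError):
    """Trade data is irreconcilable (e.g. exports from zero supply)."""


class TracingError(FpmError):
    """The origin-tracing linear system cannot be solved."""


class IntensityError(FpmError):
    """A yield or water coefficient needed for conversion is missing/zero."""


class GrazingError(FpmError):
    """Grazing accounting is undefined for the given country inputs."""


class StructureError(FpmError):
    """A supply--use system is structurally invalid."""


class NonProductiveError(FpmError):
    """The technical-coefficient matrix has spectral radius >= 1."""


class IndexingError(FpmError):
    """Demand refers to a commodity unknown to the Leontief system."""


class ClassificationError(FpmError):
    """A final-demand product has no food/non-food class."""


class ReportingError(FpmError):
    """A reporting operation received invalid inputs."""


class ComparisonError(FpmError):
    """Model results cannot be compared (mismatched indicator sets)."""
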