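"""Exception hierarchy shared across the package."""


class TricoordError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(TricoordError, ValueError):
    """A simulation or run configuration violates its invariants."""


class DegenerateIndicatorError(TricoordError, ValueError):
    """An indicator is constant within its standardization pool."""


class UndefinedWeightsError(TricoordError, ValueError):
    """All indicators in a block carry zero information; weights undefined."""


class UndefinedCouplingError(TricoordError, ValueError):
    """Coupling degree is undefined (all subsystem scores are zero)."""


class PartitionError(TricoordError, ValueError):
    """Too few distinct values to form the requested tier partition."""


class EstimationError(TricoordError, RuntimeError):
    """A statistical estimation step failed or did not converge."""


class GeometryError(TricoordError, ValueError):
    """Spatial-weight construction received inconsistent geometry."""


class DependencyError(TricoordError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""


class CompletenessError(TricoordError, ValueError):
    """A panel is missing required unit-year observations."""
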