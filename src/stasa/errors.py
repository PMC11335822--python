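"""Exception hierarchy shared across the package."""


class StasaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(StasaError):
    """A required column could not be resolved in a fixation table."""


class ScanpathValidationError(StasaError):
    """A scanpath violates the temporal-ordering or duration invariants."""


class InfeasibleDurationsError(StasaError):
    """Fixation durations exceed the total viewing time."""


class ParameterError(StasaError):
    """An algorithm parameter is outside its valid range."""


class DegenerateClusterError(StasaError):
    """A point set is too small or collinear to bound with a polygon."""


class DegenerateRegionError(StasaError):
    """A region has zero area, so similarity or centroid is undefined."""


class EmptyRepresentativeError(StasaError):
    """No short-time AOI survived interval detection at the given threshold."""
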