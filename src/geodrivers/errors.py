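"""Exception hierarchy shared across the package."""


class GeodriversError(Exception):
    """Base class for all package errors."""


class SchemaError(GeodriversError):
    """A required column or mapping is missing from an input file."""


class ValidationError(GeodriversError):
    """Input data violate a documented invariant (duplicates, bad values)."""


class WeightsError(GeodriversError):
    """A spatial weights matrix cannot be built or is degenerate."""


class NumericalError(GeodriversError):
    """A computation failed for numerical reasons (singularity, zero variance)."""
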