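"""Exception hierarchy shared across the package."""


class ImmunometaError(Exception):
    """Base class for all package errors."""


class SchemaError(ImmunometaError):
    """An input table is missing required columns or fields."""


class ConsistencyError(ImmunometaError):
    """Two inputs that must agree (e.g. matrix header vs metadata) do not."""


class ParseError(ImmunometaError):
    """A standard-format file could not be parsed."""


class ConfigError(ImmunometaError):
    """An invalid parameter or generator configuration."""


class DegenerateInputError(ImmunometaError):
    """Input is structurally valid but statistically degenerate."""


class InsufficientDataError(ImmunometaError):
    """Fewer observations than the operation requires."""


class PipelineError(ImmunometaError):
    """A pipeline stage produced an empty or unusable result."""
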