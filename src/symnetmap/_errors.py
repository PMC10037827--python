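"""Exception hierarchy shared across the pipeline stages."""


class SymnetmapError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(SymnetmapError):
    """A configuration value is missing, unknown, or out of range."""


class SchemaError(SymnetmapError):
    """Tabular input does not match the expected schema (columns, indices)."""


class DegenerateInputError(SymnetmapError):
    """Input is formally valid but carries no usable signal
    (all-zero map, zero-variance series, perfectly correlated columns)."""


class CollinearityError(SymnetmapError):
    """Design matrix is rank deficient; carries the aliased term names."""

    def __init__(self, message, aliased=()):
        super().__init__(message)
        self.aliased = tuple(aliased)


class SampleSizeError(SymnetmapError):
    """Too few observations for the requested model."""
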