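"""Exception hierarchy shared across the pipeline."""


class SporesolError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SporesolError):
    """A required column is missing or a mapping is invalid."""


class IntegrityError(SporesolError):
    """Duplicate keys or otherwise inconsistent records."""


class ValidationError(SporesolError):
    """A value violates a documented bound or invariant."""


class ParameterError(SporesolError):
    """An operation was called with an unusable parameter."""


class FitError(SporesolError):
    """A model fit failed or the data do not support fitting."""


class ConfigError(SporesolError):
    """Pipeline configuration is malformed."""
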