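"""Exception hierarchy shared across the package."""


class EcostructError(Exception):
    """Base class for all package errors."""


class SchemaError(EcostructError):
    """A required column or field is missing from an input table."""


class ValidationError(EcostructError):
    """Input data violates a documented invariant."""


class ParameterError(EcostructError):
    """A function argument is outside its documented domain."""


class ConfigError(EcostructError):
    """A configuration object is internally inconsistent."""
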