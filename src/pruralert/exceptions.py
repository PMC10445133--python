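"""Exception types shared across the package."""


class PruralertError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PruralertError, ValueError):
    """A configuration value is invalid; the message names the field."""


class InputError(PruralertError, ValueError):
    """Input data violate a precondition (shape, contiguity, range)."""


class UndefinedEstimateError(PruralertError, ValueError):
    """A 2x2 table has an empty row or column, so the odds ratio is undefined."""
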