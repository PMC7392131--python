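"""Exception hierarchy shared across modules."""


class CartrakeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CartrakeError):
    """Invalid configuration value; message names the offending field."""


class FormatError(CartrakeError):
    """Malformed input file; message carries the row number where known."""


class DivergenceError(CartrakeError):
    """Raking cannot proceed (zero weighted cell with a positive target)."""


class ValidationError(CartrakeError):
    """Input data violates an operation precondition."""
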