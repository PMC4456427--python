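"""Exception hierarchy shared across the toolkit."""


class EcisError(Exception):
    """Base class for all toolkit errors."""


class FormatError(EcisError):
    """A file does not conform to a documented dialect."""


class DataError(EcisError):
    """Input data violate a precondition (duplicates, gaps, too short...)."""


class ChannelLookupError(EcisError, KeyError):
    """Requested well or frequency is not present in the series."""


class DomainError(EcisError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class CalibrationError(EcisError):
    """Calibration constants are inconsistent (e.g. C_free <= C_confluent)."""


class FitError(EcisError):
    """A fit was consumed in an unusable state (unconverged / degenerate)."""


class ConfigError(EcisError):
    """A simulation or pipeline configuration is invalid."""
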