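"""Exception hierarchy shared across the package."""


class OiloadError(Exception):
    """Base class for all package errors."""


class InvalidInputError(OiloadError, ValueError):
    """An argument violates a documented precondition."""


class StateError(OiloadError, RuntimeError):
    """An operation was called on an object in the wrong state."""


class ParseError(OiloadError, ValueError):
    """A file could not be parsed; message names the offending line."""


class DegenerateDataError(OiloadError, ValueError):
    """Data has no variation where the requested statistic needs some."""


class ConfigurationError(OiloadError, KeyError):
    """A lookup key has no matching configuration entry."""
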