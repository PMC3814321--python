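"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config 2, data 3, model 4).
"""


class TloxtraceError(Exception):
    """Base class for all package errors."""


class ConfigError(TloxtraceError):
    """Malformed or inconsistent configuration."""


class DataError(TloxtraceError):
    """Input table violates the expected schema or is empty/degenerate."""


class ModelError(TloxtraceError):
    """Model parameter or state outside its mathematical domain."""


class SaturationError(ModelError):
    """Labeled fraction at (or numerically at) 1: proliferative history
    is unidentifiable because the cumulative labeling curve has flattened."""
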