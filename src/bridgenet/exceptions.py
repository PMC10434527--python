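"""Exception hierarchy.

All package errors derive from :class:`BridgenetError` so callers can catch
one base class; the CLI maps :class:`ConfigError` to exit code 2 and every
other package error to exit code 3.
"""


class BridgenetError(Exception):
    """Base class for all bridgenet errors."""


class SchemaError(BridgenetError):
    """Input columns do not match the codebook (unknown or missing items)."""


class ValidationError(BridgenetError):
    """A value violates its declared range or type."""


class EmptyDataError(BridgenetError):
    """An operation received (or produced) a dataset with no usable rows."""


class EstimationError(BridgenetError):
    """Numerical failure during network estimation (non-PD, singular, ...)."""


class ConfigError(BridgenetError):
    """Invalid pipeline or bootstrap configuration, detected before compute."""
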