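"""Exception hierarchy shared across the package.

All are ValueError subclasses so callers that only care about "bad input"
can catch one base class.
"""


class TwoflashError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(TwoflashError):
    """Invalid configuration: unknown preset, bad factor, malformed pattern."""


class RangeError(TwoflashError):
    """Numeric argument outside its valid domain."""


class DataError(TwoflashError):
    """Input data violates a structural contract (missing sector, bad mask)."""


class DegenerateInputError(TwoflashError):
    """Statistically degenerate input (zero-variance group, all segments bad)."""


class PairingError(TwoflashError):
    """Paired comparison requested on inputs that are not paired."""
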