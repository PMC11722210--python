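"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes (config 2, data 3, numerics 4);
library callers can catch them individually.
"""


class TsselectError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TsselectError):
    """A configuration file or option set is invalid."""


class DataError(TsselectError, ValueError):
    """Input data violate a documented precondition or invariant."""


class NumericalError(TsselectError, RuntimeError):
    """A numerical routine (integrator, optimizer) failed to produce a result."""
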