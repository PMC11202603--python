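"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes (configuration errors -> 2,
input/data errors -> 3); library users catch them like any ValueError.
"""


class SonoacError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(SonoacError):
    """A spec/config object is internally inconsistent or infeasible."""


class InputError(SonoacError):
    """Runtime data handed to an operation violates its contract."""


class DegenerateInputError(InputError):
    """Statistically degenerate data (zero variance, single class, ...)."""
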