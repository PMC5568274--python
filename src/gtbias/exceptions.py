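"""Exception hierarchy.

Each error class carries the process exit code the command-line layer uses,
so that configuration, data and numerical failures are distinguishable to
calling scripts.
"""


class GtbiasError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(GtbiasError):
    """Invalid or unknown configuration value; the message names the key."""

    exit_code = 2


class DataError(GtbiasError):
    """Malformed or inconsistent input data (CSV schema, interval structure)."""

    exit_code = 3


class NumericalError(GtbiasError):
    """Quadrature or optimisation failure with diagnostics in the message."""

    exit_code = 4


class FitError(NumericalError):
    """A model fit could not be attempted (e.g. no events in the design)."""
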