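"""Exception hierarchy shared across the pipeline stages."""


class BPCentileError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BPCentileError):
    """A configuration value is invalid; the message names the offending field."""


class DataError(BPCentileError):
    """Input data violate a stage's preconditions (missing values, bad rows)."""


class RangeError(BPCentileError):
    """A lookup (age, percentile, ...) falls outside the supported range."""


class CoverageError(BPCentileError):
    """A reference model does not cover the requested stratum."""


class SingularityError(BPCentileError):
    """A design matrix is rank deficient; the message names collinear columns."""
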