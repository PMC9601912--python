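"""Exception hierarchy.

Data errors (bad traces, malformed files) and configuration errors (impossible
geometry, bad analysis requests) are kept distinct so the command-line layer
can map them to exit codes 1 and 2 respectively.
"""


class SpiralTestError(Exception):
    """Base class for all package errors."""


class DataError(SpiralTestError):
    """A problem with input data (trace, cohort, summaries)."""


class ConfigError(SpiralTestError):
    """A problem with parameters or configuration."""


class TraceFormatError(DataError):
    """A trace/cohort file could not be parsed; names the offending line."""


class TraceValidationError(DataError):
    """Parsed values violate a trace invariant (e.g. decreasing timestamps)."""


class DegenerateTraceError(DataError):
    """Trace has fewer than two samples and cannot be scored or written."""


class UndefinedAngleError(DataError):
    """A sample coincides with the spiral center; its polar angle is undefined."""


class InsufficientCoverageError(DataError):
    """Trace covers too little of the spiral sweep to be scored."""


class SpiralConfigError(ConfigError):
    """Reference-spiral geometry is impossible (outer radius <= inner)."""


class AngleDomainError(ConfigError):
    """Angle outside the spiral's angular sweep."""


class GroupingError(ConfigError):
    """Grouping column does not have exactly two levels."""


class InsufficientDataError(DataError):
    """Too few values for a statistic (n < 2)."""


class SummaryInputError(DataError):
    """Operation needs raw per-subject values but only summaries were given."""


class UndefinedTTestError(DataError):
    """t statistic undefined (zero standard error and zero mean difference)."""
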