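"""Exception hierarchy."""


class EEGFatigueError(Exception):
    """Base class for package errors."""


class ScheduleError(EEGFatigueError):
    """Invalid session schedule (durations, ordering, sampling rate)."""


class ParseError(EEGFatigueError):
    """A recording file could not be validated."""


class PartitionError(EEGFatigueError):
    """A recording is too short (or inconsistent) to partition into events."""


class AggregationError(EEGFatigueError):
    """Feature aggregation received no input."""


class ThresholdError(EEGFatigueError):
    """Threshold derivation selected no scores."""


class ConfigurationError(EEGFatigueError):
    """Invalid run or cohort configuration."""


class OversamplingError(EEGFatigueError):
    """Minority oversampling cannot proceed (too few minority samples)."""


class MetricError(EEGFatigueError):
    """Metrics requested from empty or inconsistent predictions."""
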