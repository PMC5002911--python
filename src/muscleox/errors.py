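"""Exception hierarchy.

``DataError`` and its subclasses signal problems with the input images or
time courses; ``ConfigError`` signals a bad run configuration before any
computation starts; ``StatsError`` signals a statistic that cannot be
assessed (too few subjects, zero variance, ...).
"""


class MuscleoxError(Exception):
    """Base class for all package errors."""


class DataError(MuscleoxError, ValueError):
    """Invalid or inconsistent input data."""


class NotATimeSeriesError(DataError):
    """A 4-D BOLD series was expected but the image is not one."""


class MaskError(DataError):
    """Invalid label mask or legend (float-typed mask, missing label, empty VOI)."""


class AlignmentError(DataError):
    """Series and mask do not share spatial geometry."""


class ProtocolError(DataError):
    """Protocol timing is inconsistent with the data or with itself."""


class ConfigError(MuscleoxError):
    """Invalid run configuration (missing paths, bad options)."""


class StatsError(MuscleoxError):
    """A statistic is not assessable on the given records."""
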