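"""Exception hierarchy for h3k4diff.

Every error raised on bad user input derives from H3K4DiffError so callers
can catch one type at the CLI boundary.
"""


class H3K4DiffError(Exception):
    """Base class for all package errors."""


class ConfigError(H3K4DiffError):
    """Invalid configuration value or combination."""


class CapacityError(ConfigError):
    """A simulated genome is too small for the requested content.

    The message names the limiting parameter.
    """


class PlacementError(H3K4DiffError):
    """Peak placement is incompatible with the annotation geometry."""


class FormatError(H3K4DiffError):
    """A file or track violates the expected dialect."""


class DataError(H3K4DiffError):
    """Inconsistent or missing data values."""


class MappingError(DataError):
    """Chromosome naming mismatch between inputs."""


class UndefinedStatisticError(H3K4DiffError):
    """A ratio or percentage is requested over an empty denominator.

    Raised instead of silently returning 0, so an empty filtered set is
    distinguishable from a genuinely zero fraction.
    """


class DegenerateDataError(DataError):
    """Statistical test input with no usable variation."""


class EmptyTrackError(ConfigError):
    """A coverage track would contain no reads."""
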