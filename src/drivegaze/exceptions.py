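"""Exception hierarchy for drivegaze."""


class DriveGazeError(Exception):
    """Base class for all drivegaze errors."""


class GeometryError(DriveGazeError):
    """Invalid screen geometry (non-positive dimension or pixel count)."""


class FormatError(DriveGazeError):
    """Malformed trace, scenario, or event file."""


class ConfigError(DriveGazeError):
    """Invalid detection or generator configuration."""


class InsufficientDataError(DriveGazeError):
    """An operation was given fewer samples or records than it needs."""


class TrackCoverageError(DriveGazeError):
    """An object's screen-position track is undefined at a required time."""


class CodingError(DriveGazeError):
    """A raw cohort table contains a label the design coding does not know."""


class RankDeficiencyError(DriveGazeError):
    """The coded design matrix is singular (collinear or constant columns)."""


class AmbiguityWarning(UserWarning):
    """A manual response falls inside the windows of several objects."""
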