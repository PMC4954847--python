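"""Exception hierarchy with distinct CLI exit codes per failure class."""


class PipelineError(Exception):
    """Base class for anticipated pipeline failures."""

    exit_code = 1


class MissingInputError(PipelineError):
    """A required file, column or mask could not be resolved."""

    exit_code = 2


class GridMismatchError(PipelineError):
    """Volumes entering a joint analysis disagree in shape, voxel size or space."""

    exit_code = 3


class UnscorableSessionError(PipelineError):
    """A startle session cannot be scored (e.g. no startle-alone trials)."""

    exit_code = 4


class InsufficientSubjectsError(PipelineError):
    """Too few subjects for the requested group statistic."""

    exit_code = 5


class UndefinedStatisticError(PipelineError, ValueError):
    """A statistic is undefined for the given input (zero denominator etc.)."""

    exit_code = 6
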