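"""Exception types shared across the package."""


class ScoreReconError(Exception):
    """Base class for all scorerecon errors."""


class DegenerateInputError(ScoreReconError, ValueError):
    """Input is formally valid but degenerate (constant image, p_e = 1, empty join)."""


class TrainingFailure(ScoreReconError, RuntimeError):
    """Score-model training diverged.

    Carries the last finite-loss checkpoint so a run can be resumed or
    inspected.
    """

    def __init__(self, message, last_checkpoint=None, step=None):
        super().__init__(message)
        self.last_checkpoint = last_checkpoint
        self.step = step


class SamplingFailure(ScoreReconError, RuntimeError):
    """Annealed Langevin trajectory produced a non-finite iterate."""

    def __init__(self, message, level=None, step=None):
        super().__init__(message)
        self.level = level
        self.step = step
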