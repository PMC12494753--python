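"""Exception hierarchy for tsgate."""


class TsgateError(Exception):
    """Base class for all tsgate errors."""


class DimensionError(TsgateError, ValueError):
    """A shape or dimension argument is invalid or incompatible."""


class DatasetError(TsgateError, ValueError):
    """A dataset violates its invariants (labels, masks, class coverage)."""


class SpecError(TsgateError, ValueError):
    """A synthetic-data specification is degenerate or inconsistent."""


class SubsetError(TsgateError, ValueError):
    """A channel-subset operation cannot be performed."""


class TrainingError(TsgateError, RuntimeError):
    """Training diverged or could not proceed.

    Carries the epoch index at which the failure was detected.
    """

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class StatsError(TsgateError, ValueError):
    """A statistical test was refused (too few pairs, degenerate variance)."""
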