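"""Exception hierarchy for pipeline contract violations."""


class NeurosyncError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NeurosyncError, ValueError):
    """An argument violates an operation precondition."""


class InvalidStateError(NeurosyncError, RuntimeError):
    """An operation was applied to an object in the wrong state
    (e.g. convolving an already-convolved regressor)."""


class UndefinedStatisticError(NeurosyncError, ValueError):
    """A statistic is undefined for the given input (e.g. ICC of
    constant traces with zero total variance)."""


class InsufficientCoverageError(NeurosyncError, ValueError):
    """A rating trace is too short to cover the stimulus interval."""


class DesignDegenerateError(NeurosyncError, ValueError):
    """A design or covariate matrix is rank deficient."""


class ResolutionError(NeurosyncError, ValueError):
    """Too few permutations to resolve the requested alpha level."""
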