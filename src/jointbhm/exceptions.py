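"""Exception types shared across the package."""


class JointBHMError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(JointBHMError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(JointBHMError, ValueError):
    """Input data are degenerate (e.g. a constant predictor column)."""


class SpecError(JointBHMError, ValueError):
    """A model specification references unknown covariates or is inconsistent."""


class UnsupportedPriorError(JointBHMError, ValueError):
    """A sampler or check cannot operate under the requested prior."""


class InitializationError(JointBHMError, RuntimeError):
    """A sampler could not find a valid starting state."""


class InsufficientChainsError(JointBHMError, ValueError):
    """A diagnostic requires more chains than were supplied."""


class TuningFailureError(JointBHMError, RuntimeError):
    """Sampler adaptation failed (e.g. every warm-up trajectory diverged)."""
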