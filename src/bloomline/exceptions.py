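"""Exception types shared across the package."""


class BloomlineError(Exception):
    """Base class for package-specific errors."""


class InvalidParameterError(BloomlineError, ValueError):
    """A parameter violates its documented domain (non-positive fold, unknown site, ...)."""


class DegenerateInputError(BloomlineError, ValueError):
    """Input is structurally unusable (all-zero sample with no spike, all-zero compound, ...)."""


class RankDeficientError(BloomlineError, ValueError):
    """A design matrix is rank deficient; the message names the aliased term."""


class ConvergenceError(BloomlineError, RuntimeError):
    """An iterative fit failed to converge (e.g. monotone Cox partial likelihood)."""
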