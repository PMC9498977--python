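"""Exception hierarchy for the pipeline."""


class HapticubeError(Exception):
    """Base class for all package errors."""


class ParseError(HapticubeError):
    """A session or annotations file could not be parsed."""


class ValidationError(HapticubeError):
    """Input violates a documented invariant (monotonic time, unit norm, ...)."""


class TrialTooShortError(HapticubeError):
    """Raw samples do not span at least one grid step."""


class EmptyTrialError(HapticubeError):
    """No grid sample satisfies the minimum-activity requirement."""


class MetricUndefinedError(HapticubeError):
    """A per-trial metric has no qualifying samples."""


class GenerationError(HapticubeError):
    """A synthetic-data preset is infeasible."""
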