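"""Package-specific exception types."""


class DelayDetectError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DelayDetectError, ValueError):
    """Non-finite, out-of-range or otherwise unusable input values."""


class InvalidConfigError(DelayDetectError, ValueError):
    """A configuration (grid, catch schedule, cohort spec) is inconsistent."""


class InvalidTargetError(DelayDetectError, ValueError):
    """Tracking probability not reachable for the given psychometric curve."""


class InvalidBlockError(DelayDetectError, ValueError):
    """A trial block does not satisfy the preconditions of a QC rule."""


class InsufficientDataError(DelayDetectError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(DelayDetectError, ValueError):
    """Constant or zero-variance input where variability is required."""


class CollinearityError(DelayDetectError, ValueError):
    """Rank-deficient design matrix; carries the offending term names."""

    def __init__(self, terms, message=None):
        self.terms = list(terms)
        super().__init__(message or f"collinear model terms: {self.terms}")
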