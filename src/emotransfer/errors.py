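"""Exception hierarchy shared across the package."""


class EmotransferError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(EmotransferError, ValueError):
    """Malformed input: wrong shape, non-positive state, empty grid, bad table."""


class DomainError(EmotransferError, ValueError):
    """A parameter left its admissible domain (proportions must lie in (0, 1))."""


class NumericalError(EmotransferError, RuntimeError):
    """Integration diverged or produced non-finite values."""


class InsufficientDataError(EmotransferError, ValueError):
    """Too few observations for the requested fit."""


class CollinearityError(EmotransferError, ValueError):
    """Regression design matrix is singular or numerically rank deficient."""


class DegenerateGridError(EmotransferError, ValueError):
    """Surface fit attempted on fewer than six distinct, non-degenerate points."""


class StepSizeError(EmotransferError, ValueError):
    """Unit-step recursion overshot into non-increasing or negative values."""


class FixtureLookupError(EmotransferError, KeyError):
    """Unknown builtin fixture name."""
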