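"""Structured exceptions shared across the package."""


class BivarpedError(Exception):
    """Base class for all package errors."""


class FormatError(BivarpedError):
    """Malformed input file or field."""


class DuplicateIdError(FormatError):
    """An individual id occurs more than once."""


class RangeError(BivarpedError):
    """A numeric value lies outside its permitted range."""


class MissingError(BivarpedError):
    """Required values are all missing."""


class DegenerateError(BivarpedError):
    """Input is degenerate (constant column, zero covariance, ...)."""


class InsufficientDataError(BivarpedError):
    """Too few usable observations for the requested estimate."""


class SingularityError(BivarpedError):
    """Design matrix is rank deficient."""


class PedigreeCycleError(BivarpedError):
    """The parent-offspring graph contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"pedigree contains a cycle: {' -> '.join(map(str, self.cycle))}")


class NumericalError(BivarpedError):
    """A linear-algebra step failed (non-invertible covariance, non-PSD matrix)."""


class EmptyAfterQcError(BivarpedError):
    """All markers or all subjects were removed by quality control."""


class UnstableError(BivarpedError):
    """A resampling estimator failed on too many resamples."""


class CollinearityWarning(UserWarning):
    """Two predictors are highly correlated; estimates may be unstable."""
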