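"""Exception types shared across the pipeline."""


class MedsuppressError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MedsuppressError, ValueError):
    """An input value is outside the mathematical domain of a formula.

    The message always names the offending field so that a failure deep in a
    batch computation can be traced to a column.
    """


class MissingDataError(MedsuppressError, ValueError):
    """A required field is absent; the pipeline never imputes silently."""


class SingularDesignError(MedsuppressError, ValueError):
    """The regression design matrix is rank deficient.

    Carries the names of the collinear columns when they can be identified.
    """

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.columns = columns


class SeparationError(MedsuppressError, RuntimeError):
    """Logistic outcome is perfectly separated; no finite MLE exists."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped at max_iter without meeting its tolerance."""
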