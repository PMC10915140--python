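"""Exception hierarchy shared across the package."""


class SmrhythmError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SmrhythmError, ValueError):
    """A parameter value violates its documented constraints."""


class InsufficientDataError(SmrhythmError):
    """Not enough samples/rows to perform the requested operation."""


class InfeasiblePlacementError(SmrhythmError):
    """Requested burst load cannot be placed without overlap."""


class FitFailureError(SmrhythmError):
    """An iterative fit failed to converge.

    Carries whatever partial result was available at the point of failure
    in the ``partial`` attribute (may be ``None``).
    """

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


class DegenerateDesignError(SmrhythmError):
    """A design matrix column has zero variance or is otherwise unusable."""


class UndefinedPercentError(SmrhythmError):
    """Percent change is undefined (non-positive reference level)."""


class InvalidTableError(SmrhythmError, ValueError):
    """A contingency table has a zero marginal or invalid shape."""


class SchemaError(SmrhythmError):
    """An input table is missing required columns."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing required columns: {', '.join(self.missing)}")
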