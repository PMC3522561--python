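"""Exception hierarchy for the odesd solver stack."""


class OdesdError(Exception):
    """Base class for all package-specific errors."""


class ModelEvaluationError(OdesdError):
    """A model evaluator returned a non-finite value.

    Carries the index of the first offending component so the failure can be
    traced back to a species/equation.
    """

    def __init__(self, what: str, index):
        self.what = what
        self.index = index
        super().__init__(f"{what} produced a non-finite value at component index {index}")


class ModelValidationError(OdesdError):
    """An analytic derivative disagrees with its finite-difference check."""


class CompilationError(OdesdError):
    """The symbolic model cannot be compiled (e.g. undeclared symbols)."""


class UnsupportedModelError(OdesdError):
    """The model lacks an evaluator required by the requested operation."""


class StepFailureError(OdesdError):
    """A single integration step failed; the driver reduces h and retries."""


class NewtonMatrixSingularError(StepFailureError):
    """The Newton iteration matrix is singular or non-finite."""


class NewtonDivergenceError(StepFailureError):
    """The simplified Newton iteration diverged or failed to converge."""


class IllConditionedRuleError(OdesdError):
    """Step-size ratio outside the range where the g5 weights are trustworthy."""

    def __init__(self, ratio: float):
        self.ratio = ratio
        super().__init__(
            f"step ratio h/h_prev = {ratio:g} outside the supported range; "
            "falling back to the predictor-based error estimate"
        )


class IntegrationFailure(OdesdError):
    """Integration could not be continued (step size underflow)."""
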