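"""Exception hierarchy for expertchoice."""


class ExpertChoiceError(Exception):
    """Base class for all expertchoice errors."""


class UnknownLevelError(ExpertChoiceError):
    """A level label does not exist for the named factor."""

    def __init__(self, factor: str, level: str):
        self.factor = factor
        self.level = level
        super().__init__(f"unknown level {level!r} for factor {factor!r}")


class InfeasibleProfileError(ExpertChoiceError):
    """A profile violates one or more feasibility constraints."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "profile violates constraint(s): "
            + "; ".join(str(v) for v in self.violations)
        )


class EmptyFeasibleSetError(ExpertChoiceError):
    """The constraints leave no feasible profile."""


class SingularDesignError(ExpertChoiceError):
    """The design's information matrix is singular (non-identifiable design)."""


class RankDeficiencyError(ExpertChoiceError):
    """The coded design matrix of a dataset is rank deficient."""

    def __init__(self, collinear_columns):
        self.collinear_columns = list(collinear_columns)
        super().__init__(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(self.collinear_columns)
        )


class SeparationError(ExpertChoiceError):
    """Weights diverged during estimation: possible complete separation."""


class ConvergenceError(ExpertChoiceError):
    """Newton-Raphson failed to reach the gradient tolerance."""

    def __init__(self, message, trace=None):
        self.trace = trace or []
        super().__init__(message)


class DegenerateModelError(ExpertChoiceError):
    """All part-worth ranges are zero; relative importance is undefined."""


class FileFormatError(ExpertChoiceError):
    """A file does not conform to the expected schema."""
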