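"""Exception hierarchy for trialdyn.

All package-specific errors derive from :class:`TrialDynError` so callers can
catch everything with one clause; the subclasses distinguish configuration
problems from data-format problems and numerically degenerate inputs.
"""


class TrialDynError(Exception):
    """Base class for all trialdyn errors."""


class ConfigurationError(TrialDynError):
    """A generator or pipeline configuration violates its invariants."""


class FormatError(TrialDynError):
    """An input file does not conform to the expected CSV dialect/grid."""


class DomainError(TrialDynError):
    """An argument is outside the domain of an operation (e.g. unknown
    electrode, window outside the epoch, fewer trials than bins)."""


class DegenerateInputError(TrialDynError):
    """An input is numerically degenerate (zero variance, perfect
    collinearity) so the requested statistic is undefined."""


class SingularDesignError(TrialDynError):
    """The regression design matrix is rank deficient."""


class AlignmentError(TrialDynError):
    """Trial sets of two objects that must describe the same trials differ."""


class PipelineError(TrialDynError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
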