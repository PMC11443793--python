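"""Exception types shared across the package."""


class RbaBenchError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RbaBenchError, ValueError):
    """A parameter is outside its documented domain."""


class FeasibilityError(RbaBenchError, RuntimeError):
    """Constrained penetrance-table search exhausted its attempt budget.

    Attributes
    ----------
    attempts : int
        Number of candidate tables that were sampled and rejected.
    """

    def __init__(self, message: str, attempts: int):
        super().__init__(message)
        self.attempts = attempts


class DegenerateClassError(RbaBenchError, ValueError):
    """A class has too few instances for neighbor-based scoring."""


class FormatError(RbaBenchError, ValueError):
    """A dataset file violates the tab-delimited genotype format."""


class IntegrityError(RbaBenchError, RuntimeError):
    """An internal consistency check failed (e.g. missing predictive feature)."""
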