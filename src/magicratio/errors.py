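"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: UsageError -> 2, NumericalError -> 3.
"""


class MagicRatioError(Exception):
    """Base class for all package errors."""


class UsageError(MagicRatioError):
    """Invalid user input: bad parameters, malformed files, unknown options."""


class NumericalError(MagicRatioError):
    """A numerical procedure failed (non-convergence, blow-up, degeneracy)."""


class IntegrationBlowUpError(NumericalError):
    """Langevin integration produced non-finite coordinates."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"integration blew up at step {step}")


class PackingError(UsageError):
    """Requested configuration cannot be packed into the box."""


class ConvergenceError(NumericalError):
    """Iterative solver did not reach the requested residual."""

    def __init__(self, message: str, residuals=None):
        self.residuals = residuals
        super().__init__(message)
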