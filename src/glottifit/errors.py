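"""Exception hierarchy for glottifit."""


class GlottifitError(Exception):
    """Base class for all glottifit errors."""


class DomainError(GlottifitError, ValueError):
    """An input value lies outside the mathematically valid domain."""


class DegenerateInputError(GlottifitError, ValueError):
    """Input signal is degenerate (e.g. all-zero trajectories)."""


class NoOscillationError(GlottifitError, ValueError):
    """Signal carries no oscillatory energy above the noise floor."""


class InsufficientCyclesError(GlottifitError, ValueError):
    """Fewer complete oscillation cycles than the analysis requires."""


class IntegrationBlowupError(GlottifitError, RuntimeError):
    """The ODE integration produced a non-finite state.

    Carries the simulation time (ms) at which the blow-up was detected.
    """

    def __init__(self, time_ms: float):
        self.time_ms = float(time_ms)
        super().__init__(f"integration blew up at t = {time_ms:.3f} ms")


class SearchFailureError(GlottifitError, RuntimeError):
    """Every objective evaluation in a search was non-finite."""


class FitFailureError(GlottifitError, RuntimeError):
    """No optimizer run produced a finite selection metric."""


class ParseError(GlottifitError, ValueError):
    """A trajectory CSV or result JSON failed validation."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
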