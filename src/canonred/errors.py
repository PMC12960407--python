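"""Exception hierarchy for canonred.

All package-specific failures derive from :class:`CanonredError` so callers
can catch one base class.  Reduction refusals carry the offending variable
name, because batch drivers (ranking, CLI) report it to the user.
"""

from __future__ import annotations


class CanonredError(Exception):
    """Base class for all canonred errors."""


class ValidationError(CanonredError):
    """A model or document violates a structural invariant."""


class ParseError(ValidationError):
    """A model document could not be parsed; names the offending field."""


class DomainError(CanonredError):
    """Evaluation outside the model's domain (e.g. non-positive state under
    a fractional kinetic order)."""


class NormalizationError(CanonredError):
    """A term is not a power product and cannot be canonically normalized."""


class NotReducible(CanonredError):
    """The requested variable cannot be eliminated by its nullcline."""

    def __init__(self, variable: str, reason: str = ""):
        self.variable = variable
        self.reason = reason
        msg = f"variable {variable!r} cannot be reduced"
        if reason:
            msg += f": {reason}"
        super().__init__(msg)


class AlreadyDecoupled(NotReducible):
    """The variable appears in no equation; its ODE is already decoupled."""


class NotSolvable(NotReducible):
    """No closed-form nullcline solution was found (GMA/general models)."""


class CyclicDependency(CanonredError):
    """Nullcline solutions reference each other; use a simultaneous solve."""


class SingularElimination(CanonredError):
    """The joint nullcline system of the eliminated block is singular."""


class CannotCollapse(CanonredError):
    """Symbolic parameters without numeric bindings cannot be collapsed."""


class GenerationFailed(CanonredError):
    """The synthetic-model generator exhausted its retry budget."""

    def __init__(self, attempts: int, reason: str = ""):
        self.attempts = attempts
        super().__init__(
            f"model generation failed after {attempts} attempts"
            + (f": {reason}" if reason else "")
        )


class NoUniqueSteadyState(CanonredError):
    """The S-system exponent-difference matrix is singular; no unique
    positive steady state exists."""


class IntegrationError(CanonredError):
    """Numerical integration failed before reaching the end of the span."""

    def __init__(self, message: str, last_time: float | None = None):
        self.last_time = last_time
        super().__init__(message)
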