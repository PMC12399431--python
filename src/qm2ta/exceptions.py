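"""Exception hierarchy shared by all pipeline stages."""


class QM2TAError(Exception):
    """Base class for all package errors."""


class FormatError(QM2TAError):
    """A model or table file could not be parsed, or violates a structural
    invariant (e.g. a reaction with lb > ub)."""


class ConfigurationError(QM2TAError):
    """Inconsistent or incomplete configuration (missing objective,
    unsatisfiable feasibility guard, bad threshold)."""


class DomainError(QM2TAError, ValueError):
    """An argument is outside its mathematical domain (p-value not in (0,1],
    non-positive cell count, fraction outside [0,1], ...)."""


class ModelLookupError(QM2TAError, KeyError):
    """A referenced gene, metabolite, reaction or condition does not exist."""


class InfeasibleError(QM2TAError):
    """The optimization problem has no feasible point under the current
    constraints."""

    def __init__(self, message: str, hint: str | None = None):
        super().__init__(message if hint is None else f"{message} ({hint})")
        self.hint = hint


class UnboundedError(QM2TAError):
    """The flux polytope is unbounded along some direction."""

    def __init__(self, message: str, reactions: list[str] | None = None):
        super().__init__(message)
        self.reactions = list(reactions or [])


class NumericalError(QM2TAError):
    """A solver failed to converge or returned an inconsistent certificate."""


class GenerationError(QM2TAError):
    """A synthetic fixture could not be generated under its constraints."""


class ScoringError(QM2TAError):
    """Target scoring is undefined (e.g. TS_base = 0)."""
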