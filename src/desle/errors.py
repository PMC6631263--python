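"""Typed errors and warnings raised across the package."""


class DesleError(Exception):
    """Base class for all package-specific errors."""


class ThermoDomainError(DesleError, ValueError):
    """An argument lies outside the physical domain of a thermodynamic relation
    (negative temperature, mole fraction outside [0, 1], ...)."""


class NoPhysicalLiquidusError(DesleError, ArithmeticError):
    """The liquidus equation has no solution with T > 0 at the requested
    composition.

    For temperature-independent Redlich-Kister excess terms this happens when
    the excess contribution is so negative that dHm + P(xj) <= 0: the
    crystallizing component would remain dissolved down to absolute zero,
    which the model cannot represent.
    """

    def __init__(self, x: float, numerator: float):
        self.x = x
        self.numerator = numerator
        super().__init__(
            f"no physical liquidus at x = {x:.6g}: "
            f"dHm + P(xj) = {numerator:.6g} J/mol <= 0"
        )


class NoEutecticError(DesleError, RuntimeError):
    """The two liquidus branches never intersect on (0, 1)."""


class FitError(DesleError, RuntimeError):
    """An optimization or regression failed to produce a usable result."""


class DegenerateFitError(FitError):
    """Too few (or collinear) data points for the requested regression."""


class SLEParseError(DesleError, ValueError):
    """A solid-liquid-equilibrium CSV table failed validation.

    Carries the offending line numbers (1-based, header = line 1) so callers
    can report exactly which rows are malformed.
    """

    def __init__(self, message: str, lines: list[int] | None = None):
        self.lines = lines or []
        super().__init__(message)


class PositiveDeviationWarning(UserWarning):
    """A Redlich-Kister coefficient set implies positive deviation from
    ideality (some gamma > 1); accepted, but outside the screened regime."""
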