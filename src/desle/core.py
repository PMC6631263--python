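"""Pure-component melting thermodynamics and the liquidus equation.

The liquidus temperature of a simple eutectic branch follows from equating
the chemical potential of the crystallizing component i in the pure solid
with that in the liquid solution, referenced to the subcooled liquid:

    ln(x_i * gamma_i) = -dHm_i/(R T) * (1 - T/Tm_i)
                        - dCp_i/R * (1 - Tm_i/T + ln(Tm_i/T))

where dHm_i and Tm_i are the melting enthalpy and temperature of pure i and
dCp_i = cp(liquid) - cp(solid). The dCp term is small and usually unknown;
with dCp = 0 the classic Schroeder-van Laar simplification is recovered.

Liquid-phase non-ideality is described by an empirical Redlich-Kister
polynomial in the mole fraction x_j of the *other* component,

    R T ln(gamma_i) = a * x_j**2 + b * x_j**3 + c * x_j**4

whose coefficients carry units of J/mol and no direct physical meaning:
negative values encode favored unlike-pair interactions (gamma < 1).

Because the excess term R T ln(gamma) above is temperature-independent, the
dCp = 0 liquidus admits a closed form,

    T = (dHm + P(x_j)) / (dHm/Tm - R ln x),    P(x_j) = a x_j^2 + b x_j^3 + c x_j^4

which is used whenever dCp = 0; the full equation is solved by bracketed
root finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import R
from .errors import NoPhysicalLiquidusError, ThermoDomainError

__all__ = [
    "MeltingProperties",
    "RKCoefficients",
    "SLEPoint",
    "walden_enthalpy",
    "enthalpy_from_entropy",
    "rk_excess",
    "rk_log_gamma",
    "liquidus_temperature",
    "full_liquidus_residual",
    "liquidus_temperature_full",
    "gamma_from_sle_point",
    "gamma_reference_shift",
]

_LIQUIDUS_TOL_K = 1e-8  # absolute tolerance of the bracketed liquidus root


@dataclass(frozen=True)
class MeltingProperties:
    """Reference-state melting properties of a pure component.

    Parameters
    ----------
    Tm : float
        Melting temperature, K. Must be positive.
    dHm : float
        Melting enthalpy, J/mol. Must be positive.
    dCp : float, optional
        Heat-capacity difference liquid minus solid, J/(mol K). Default 0,
        which drops the heat-capacity correction from the liquidus equation.
    """

    Tm: float
    dHm: float
    dCp: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.Tm) and self.Tm > 0):
            raise ThermoDomainError(f"Tm must be finite and > 0, got {self.Tm}")
        if not (math.isfinite(self.dHm) and self.dHm > 0):
            raise ThermoDomainError(f"dHm must be finite and > 0, got {self.dHm}")
        if not math.isfinite(self.dCp):
            raise ThermoDomainError(f"dCp must be finite, got {self.dCp}")

    @property
    def dSm(self) -> float:
        """Melting entropy dHm/Tm, J/(mol K)."""
        return self.dHm / self.Tm


@dataclass(frozen=True)
class RKCoefficients:
    """Redlich-Kister coefficients (a, b, c) in J/mol for one liquidus branch.

    An empty coefficient tuple means ideal behavior (ln gamma = 0). Each
    branch carries its own independent set; thermodynamic cross-consistency
    between the branches (Gibbs-Duhem) is deliberately not enforced, matching
    the empirical use of the polynomial.
    """

    coeffs: tuple[float, ...] = field(default=())

    def __post_init__(self):
        cs = tuple(float(c) for c in self.coeffs)
        if len(cs) > 3:
            raise ThermoDomainError("at most three coefficients (a, b, c) supported")
        if not all(math.isfinite(c) for c in cs):
            raise ThermoDomainError(f"coefficients must be finite, got {cs}")
        object.__setattr__(self, "coeffs", cs)

    @classmethod
    def ideal(cls) -> "RKCoefficients":
        return cls(())

    @property
    def is_ideal(self) -> bool:
        return not any(self.coeffs)

    @property
    def has_positive_deviation(self) -> bool:
        """True if any coefficient is positive (can yield gamma > 1)."""
        return any(c > 0 for c in self.coeffs)

    def excess(self, xj):
        """P(xj) = a xj^2 + b xj^3 + c xj^4 in J/mol; accepts arrays."""
        xj = np.asarray(xj, dtype=float)
        out = np.zeros_like(xj)
        for k, c in enumerate(self.coeffs):
            out = out + c * xj ** (k + 2)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class SLEPoint:
    """One liquidus observation: liquid composition, temperature, and which
    solid crystallizes (branch 1 or 2). x1 is the mole fraction of
    Component 1 regardless of branch."""

    x1: float
    T: float
    branch: int = 1

    def __post_init__(self):
        if not (0.0 <= self.x1 <= 1.0):
            raise ThermoDomainError(f"x1 must lie in [0, 1], got {self.x1}")
        if not (math.isfinite(self.T) and self.T > 0):
            raise ThermoDomainError(f"T must be finite and > 0, got {self.T}")
        if self.branch not in (1, 2):
            raise ThermoDomainError(f"branch must be 1 or 2, got {self.branch}")

    @property
    def x_crystallizing(self) -> float:
        """Mole fraction of the component that crystallizes on this branch."""
        return self.x1 if self.branch == 1 else 1.0 - self.x1


def walden_enthalpy(Tm: float) -> float:
    """Melting enthalpy from the Walden rule, dHm = 54.4 * Tm (J/mol).

    The Walden rule states that rigid organic molecules share a roughly
    constant melting entropy of 54.4 J/(mol K).
    """
    if Tm < 0:
        raise ThermoDomainError(f"Tm must be >= 0, got {Tm}")
    return 54.4 * Tm


def enthalpy_from_entropy(Tm: float, dSm: float) -> float:
    """Melting enthalpy dHm = dSm * Tm (J/mol) for an assumed melting entropy."""
    if Tm < 0:
        raise ThermoDomainError(f"Tm must be >= 0, got {Tm}")
    if dSm < 0:
        raise ThermoDomainError(f"dSm must be >= 0, got {dSm}")
    return dSm * Tm


def rk_excess(xj, coeffs: RKCoefficients):
    """Excess term P(xj) = a xj^2 + b xj^3 + c xj^4, J/mol."""
    return coeffs.excess(xj)


def rk_log_gamma(xj: float, coeffs: RKCoefficients, T: float) -> float:
    """ln(gamma_i) = P(xj) / (R T) at temperature T.

    ``xj`` is the mole fraction of the *other* component. Ideal coefficients
    give exactly 0, as does the pure-component limit xj = 0.
    """
    if not (0.0 <= xj <= 1.0):
        raise ThermoDomainError(f"xj must lie in [0, 1], got {xj}")
    if T <= 0:
        raise ThermoDomainError(f"T must be > 0, got {T}")
    if not coeffs.coeffs:
        return 0.0
    return float(coeffs.excess(xj)) / (R * T)


def _closed_form_liquidus(x, props: MeltingProperties, coeffs: RKCoefficients):
    """Vectorized dCp = 0 liquidus; returns (T, numerator) arrays.

    T is NaN wherever the numerator dHm + P(1 - x) is non-positive.
    """
    x = np.asarray(x, dtype=float)
    numerator = props.dHm + coeffs.excess(1.0 - x)
    with np.errstate(invalid="ignore", divide="ignore"):
        denominator = props.dHm / props.Tm - R * np.log(x)
        T = np.where(numerator > 0, numerator / denominator, np.nan)
    return T, numerator


def liquidus_temperature(
    x: float, props: MeltingProperties, coeffs: RKCoefficients | None = None
) -> float:
    """Liquidus temperature (K) of the crystallizing component at liquid mole
    fraction ``x``, with dCp = 0.

    Uses the closed form T = (dHm + P(1-x)) / (dHm/Tm - R ln x). At x = 1 the
    pure melting temperature Tm is recovered exactly.

    Raises
    ------
    ThermoDomainError
        If x is outside (0, 1].
    NoPhysicalLiquidusError
        If the excess term is so negative that dHm + P(1-x) <= 0.
    """
    if not (0.0 < x <= 1.0):
        raise ThermoDomainError(f"x must lie in (0, 1], got {x}")
    coeffs = coeffs or RKCoefficients.ideal()
    if props.dCp != 0.0:
        raise ThermoDomainError(
            "closed-form liquidus requires dCp = 0; use liquidus_temperature_full"
        )
    T, numerator = _closed_form_liquidus(x, props, coeffs)
    if not numerator > 0:
        raise NoPhysicalLiquidusError(x, float(numerator))
    return float(T)


def full_liquidus_residual(
    x: float, T: float, props: MeltingProperties, coeffs: RKCoefficients | None = None
) -> float:
    """Residual of the full liquidus equation (dimensionless).

    Returns ln(x gamma) + dHm/(R T) (1 - T/Tm) + dCp/R (1 - Tm/T + ln(Tm/T)),
    which is zero on the liquidus. With dCp = 0 this is exactly the
    Schroeder-van Laar residual.
    """
    if x <= 0 or x > 1:
        raise ThermoDomainError(f"x must lie in (0, 1], got {x}")
    if T <= 0:
        raise ThermoDomainError(f"T must be > 0, got {T}")
    coeffs = coeffs or RKCoefficients.ideal()
    Tm, dHm, dCp = props.Tm, props.dHm, props.dCp
    res = (
        math.log(x)
        + rk_log_gamma(1.0 - x, coeffs, T)
        + dHm / (R * T) * (1.0 - T / Tm)
    )
    if dCp != 0.0:
        res += dCp / R * (1.0 - Tm / T + math.log(Tm / T))
    return res


def liquidus_temperature_full(
    x: float,
    props: MeltingProperties,
    coeffs: RKCoefficients | None = None,
    tol: float = _LIQUIDUS_TOL_K,
) -> float:
    """Liquidus temperature (K) from the full equation (dCp term included),
    by bracketed root finding on ``full_liquidus_residual`` over (0, Tm].

    With dCp = 0 this agrees with :func:`liquidus_temperature` to well below
    1e-6 K; it exists as the general solver and as an internal cross-check.
    """
    coeffs = coeffs or RKCoefficients.ideal()
    if x == 1.0:
        return props.Tm
    if not (0.0 < x < 1.0):
        raise ThermoDomainError(f"x must lie in (0, 1], got {x}")

    f = lambda T: full_liquidus_residual(x, T, props, coeffs)
    lo, hi = 1e-2, props.Tm
    f_hi = f(hi)
    # positive deviation can push the root above Tm; expand upward if needed
    n_expand = 0
    while f_hi > 0 and n_expand < 60:
        lo, hi = hi, hi * 1.5
        f_hi = f(hi)
        n_expand += 1
    f_lo = f(lo)
    if f_lo * f_hi > 0:
        raise NoPhysicalLiquidusError(x, props.dHm + float(coeffs.excess(1.0 - x)))
    return float(brentq(f, lo, hi, xtol=tol, rtol=4 * np.finfo(float).eps))


def gamma_from_sle_point(point: SLEPoint, props: MeltingProperties) -> float:
    """Experimental activity coefficient implied by one liquidus observation.

    Inverts the dCp = 0 liquidus equation for the crystallizing component:

        gamma = exp(-dHm/R * (1/T - 1/Tm)) / x

    This is the quantity the Redlich-Kister objective function is fitted to.
    Note it depends on the *assumed* melting properties: the same data point
    yields different gammas under different reference states.
    """
    x = point.x_crystallizing
    if x <= 0:
        raise ThermoDomainError("crystallizing-component mole fraction must be > 0")
    return math.exp(-props.dHm / R * (1.0 / point.T - 1.0 / props.Tm)) / x


def gamma_reference_shift(dHm_a: float, dHm_b: float, T: float, Tm: float) -> float:
    """Ratio gamma_exp(dHm_a) / gamma_exp(dHm_b) at fixed (x, T, Tm).

    Changing the assumed melting enthalpy shifts the solid/subcooled-liquid
    reference state, rescaling every experimental activity coefficient by
    exp(-(dHm_a - dHm_b)/R * (1/T - 1/Tm)) — the mechanism by which a low
    assumed enthalpy makes a component look ideal.
    """
    if T <= 0 or Tm <= 0:
        raise ThermoDomainError("temperatures must be > 0")
    return math.exp(-(dHm_a - dHm_b) / R * (1.0 / T - 1.0 / Tm))
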