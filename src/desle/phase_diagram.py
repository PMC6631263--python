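"""Binary phase-diagram assembly and eutectic-point location.

A simple eutectic binary has two liquidus branches — one per crystallizing
component — that intersect at the eutectic point (x_e, T_e), the lowest
melting composition of the mixture. The depression of T_e below the melting
point of the low-melting component, normalized as (Tm2 - T_e)/Tm2, is the
dimensionless measure of how "deep" the eutectic is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import MeltingProperties, RKCoefficients, _closed_form_liquidus, rk_log_gamma
from .errors import NoEutecticError, PositiveDeviationWarning, ThermoDomainError

__all__ = [
    "BinarySystem",
    "EutecticPoint",
    "branch_temperatures",
    "liquidus_curve",
    "eutectic_point",
    "normalized_depression",
    "phase_boundary_table",
]

logger = logging.getLogger(__name__)

#: Default number of scan points used to bracket the liquidus intersection.
DEFAULT_SCAN_POINTS = 2001

#: Tolerance on |T1 - T2| at the refined eutectic composition, K.
EUTECTIC_TOL_K = 1e-8


@dataclass(frozen=True)
class BinarySystem:
    """A binary eutectic system. Component 1 is the high-melting component
    (Tm1 >= Tm2 is enforced); each branch carries its own melting properties
    and Redlich-Kister coefficients."""

    props1: MeltingProperties
    props2: MeltingProperties
    coeffs1: RKCoefficients = RKCoefficients.ideal()
    coeffs2: RKCoefficients = RKCoefficients.ideal()
    name1: str = "component-1"
    name2: str = "component-2"

    def __post_init__(self):
        if self.props1.Tm < self.props2.Tm:
            raise ThermoDomainError(
                "Component 1 must be the high-melting component "
                f"(Tm1 = {self.props1.Tm} K < Tm2 = {self.props2.Tm} K); swap labels"
            )
        if self.coeffs1.has_positive_deviation or self.coeffs2.has_positive_deviation:
            warnings.warn(
                "positive Redlich-Kister coefficient(s): positive deviation from "
                "ideality raises the liquidus and lies outside the screened regime",
                PositiveDeviationWarning,
                stacklevel=2,
            )

    def swapped(self) -> "BinarySystem":
        """Exchange the component labels (only valid when Tm1 == Tm2)."""
        return BinarySystem(
            props1=self.props2,
            props2=self.props1,
            coeffs1=self.coeffs2,
            coeffs2=self.coeffs1,
            name1=self.name2,
            name2=self.name1,
        )


@dataclass(frozen=True)
class EutecticPoint:
    """Eutectic coordinates plus the derived depression and branch activity
    coefficients evaluated at (x1_e, Te)."""

    x1_e: float
    Te: float
    norm_depression: float
    gamma1_e: float
    gamma2_e: float

    def to_dict(self) -> dict:
        return {
            "x1_e": self.x1_e,
            "Te_K": self.Te,
            "norm_depression": self.norm_depression,
            "gamma1_e": self.gamma1_e,
            "gamma2_e": self.gamma2_e,
        }


def branch_temperatures(system: BinarySystem, branch: int, x1) -> np.ndarray:
    """Liquidus temperature of one branch on a grid of Component-1 mole
    fractions; NaN where the branch has no physical liquidus."""
    x1 = np.asarray(x1, dtype=float)
    if branch == 1:
        T, _ = _closed_form_liquidus(x1, system.props1, system.coeffs1)
    elif branch == 2:
        T, _ = _closed_form_liquidus(1.0 - x1, system.props2, system.coeffs2)
    else:
        raise ThermoDomainError(f"branch must be 1 or 2, got {branch}")
    return np.asarray(T, dtype=float)


def liquidus_curve(system: BinarySystem, branch: int, grid) -> pd.DataFrame:
    """Tabulate one liquidus branch over ``grid`` (Component-1 mole fractions).

    Returns a DataFrame with columns (x1, T_K, branch, feasible); infeasible
    compositions keep their row with T_K = NaN and feasible = False.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ThermoDomainError("composition grid must be non-empty")
    x_cryst = grid if branch == 1 else 1.0 - grid
    if np.any((x_cryst <= 0) | (x_cryst > 1)):
        raise ThermoDomainError(
            "crystallizing-component mole fraction must lie in (0, 1] on the grid"
        )
    T = branch_temperatures(system, branch, grid)
    return pd.DataFrame(
        {
            "x1": grid,
            "T_K": T,
            "branch": branch,
            "feasible": np.isfinite(T),
        }
    )


def normalized_depression(Te: float, Tm_ref: float) -> float:
    """Normalized eutectic depression (Tm_ref - Te)/Tm_ref relative to a
    reference melting temperature (conventionally the low-melting component)."""
    if Tm_ref <= 0 or Te <= 0:
        raise ThermoDomainError("temperatures must be > 0")
    return (Tm_ref - Te) / Tm_ref


def _scan_grid(n: int) -> np.ndarray:
    """Composition scan grid on (0, 1), log-dense near both pure ends.

    Ideal eutectics of very dissimilar pairs sit within ~1e-3 of a pure
    side, so a uniform grid would miss the bracket entirely.
    """
    k = max(n // 4, 10)
    lo = np.geomspace(1e-6, 0.05, k)
    mid = np.linspace(0.05, 0.95, max(n - 2 * k, 10))
    hi = 1.0 - np.geomspace(1e-6, 0.05, k)[::-1]
    return np.unique(np.concatenate([lo, mid, hi]))


def eutectic_point(system: BinarySystem, n_scan: int = DEFAULT_SCAN_POINTS) -> EutecticPoint:
    """Locate the eutectic point as the intersection of the two liquidus
    branches.

    The difference D(x) = T1(x) - T2(x) is evaluated on a dense scan grid
    (log-spaced near both pure ends); each sign change is refined by Brent
    bracketing until |D| <= 1e-8 K. If several intersections exist (possible
    with strong non-ideality) the one with the lowest temperature is returned
    and a warning is logged.

    Raises
    ------
    NoEutecticError
        If D has no sign change anywhere both branches are feasible.
    """
    grid = _scan_grid(n_scan)
    T1 = branch_temperatures(system, 1, grid)
    T2 = branch_temperatures(system, 2, grid)
    D = T1 - T2
    finite = np.isfinite(D)

    def D_scalar(x: float) -> float:
        t1 = branch_temperatures(system, 1, x)
        t2 = branch_temperatures(system, 2, x)
        return float(t1 - t2)

    roots: list[tuple[float, float]] = []  # (x_e, Te)
    idx = np.flatnonzero(finite[:-1] & finite[1:] & (D[:-1] * D[1:] <= 0))
    for i in idx:
        if D[i] == 0.0 and roots and roots[-1][0] == grid[i]:
            continue
        a, b = float(grid[i]), float(grid[i + 1])
        if D[i] == 0.0:
            x_e = a
        elif D[i + 1] == 0.0:
            x_e = b
        else:
            x_e = float(brentq(D_scalar, a, b, xtol=1e-14, rtol=4 * np.finfo(float).eps))
        Te = float(branch_temperatures(system, 2, x_e))
        if abs(D_scalar(x_e)) > EUTECTIC_TOL_K:
            continue
        if not any(abs(x_e - r[0]) < 1e-12 for r in roots):
            roots.append((x_e, Te))

    if not roots:
        raise NoEutecticError(
            "liquidus branches do not intersect on (0, 1); "
            "no simple eutectic under the given parameters"
        )
    if len(roots) > 1:
        logger.warning(
            "multiple liquidus intersections found at x1 = %s; returning the "
            "lowest-temperature one",
            [round(r[0], 6) for r in roots],
        )
    x_e, Te = min(roots, key=lambda r: r[1])

    g1 = np.exp(rk_log_gamma(1.0 - x_e, system.coeffs1, Te))
    g2 = np.exp(rk_log_gamma(x_e, system.coeffs2, Te))
    return EutecticPoint(
        x1_e=x_e,
        Te=Te,
        norm_depression=normalized_depression(Te, system.props2.Tm),
        gamma1_e=float(g1),
        gamma2_e=float(g2),
    )


def phase_boundary_table(system: BinarySystem, grid) -> pd.DataFrame:
    """Upper envelope of the two liquidus branches over ``grid``.

    Per composition, the stable liquidus is max(T1, T2) and ``stable_branch``
    the corresponding branch label; where only one branch is feasible that
    branch wins, and where neither is, the row is flagged infeasible.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ThermoDomainError("composition grid must be non-empty")
    T1 = branch_temperatures(system, 1, grid)
    T2 = branch_temperatures(system, 2, grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        T_liq = np.fmax(T1, T2)
    stable = np.where(np.isfinite(T1) & (np.nan_to_num(T1, nan=-np.inf) >= np.nan_to_num(T2, nan=-np.inf)), 1, 2)
    feasible = np.isfinite(T_liq)
    stable = np.where(feasible, stable, 0)
    return pd.DataFrame(
        {
            "x1": grid,
            "T_liquidus_K": T_liq,
            "stable_branch": stable,
            "feasible": feasible,
        }
    )
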