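"""Regression of melting properties and Redlich-Kister coefficients from
solid-liquid-equilibrium data, and the melting-enthalpy screening workflow.

Two estimation problems appear in DES thermodynamics:

* **Ideal-solubility back-fit.** Under the ideal-solution liquidus, ln(x1)
  is linear in 1/T with slope -dHm1/R and intercept dHm1/(R Tm1); ordinary
  least squares on pooled (or per-system) solubility data therefore yields
  the melting properties of a shared component that cannot be measured
  directly (e.g. thermally unstable salts such as choline chloride).

* **Activity-coefficient fit.** Given assumed melting properties, each
  liquidus observation implies an experimental activity coefficient
  gamma_exp; Redlich-Kister coefficients are found by minimizing the
  gamma-space objective OF = sum (gamma_cal - gamma_exp)^2.

Because gamma_exp depends on the assumed melting enthalpy through the
reference state, *screening* the enthalpy over a grid and refitting reveals
how the apparent (non-)ideality of a component is an artifact of that
assumption — the central cautionary result this package quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import R
from .core import (
    MeltingProperties,
    RKCoefficients,
    SLEPoint,
    _closed_form_liquidus,
    gamma_from_sle_point,
)
from .errors import DegenerateFitError, FitError, ThermoDomainError

__all__ = [
    "SLEDataset",
    "MeltingFit",
    "FitResult",
    "ScreeningRecord",
    "fit_ideal_melting_properties",
    "fit_rk_coefficients",
    "compute_aad",
    "screen_melting_enthalpy",
    "screening_table",
]


@dataclass(frozen=True)
class SLEDataset:
    """A set of liquidus observations for one binary system."""

    points: tuple[SLEPoint, ...]
    name1: str = "component-1"
    name2: str = "component-2"
    note: str = ""

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))

    def __len__(self) -> int:
        return len(self.points)

    def branch(self, branch: int) -> tuple[np.ndarray, np.ndarray]:
        """(x1, T) arrays of the points on one branch, sorted by x1."""
        pts = sorted((p for p in self.points if p.branch == branch), key=lambda p: p.x1)
        x = np.array([p.x1 for p in pts])
        T = np.array([p.T for p in pts])
        return x, T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x1": [p.x1 for p in self.points],
                "T_K": [p.T for p in self.points],
                "branch": [p.branch for p in self.points],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "SLEDataset":
        pts = tuple(
            SLEPoint(x1=float(r.x1), T=float(r.T_K), branch=int(r.branch))
            for r in df.itertuples(index=False)
        )
        return cls(points=pts, **kwargs)


@dataclass(frozen=True)
class MeltingFit:
    """Melting properties recovered from the ideal-solubility linearization."""

    dHm_hat: float  # J/mol
    Tm_hat: float  # K
    r_squared: float
    slope: float  # d ln(x1) / d (1/T), K
    intercept: float
    n_points: int


@dataclass(frozen=True)
class FitResult:
    """Redlich-Kister coefficients fitted to one dataset, with the
    gamma-space objective value and the liquidus-temperature AAD."""

    coeffs: RKCoefficients
    objective: float
    aad: float  # K; inf if any refit liquidus point is infeasible
    n_points: int
    feasible: bool = True


@dataclass(frozen=True)
class ScreeningRecord:
    """One enthalpy-screening result: the assumed melting enthalpy, the
    corresponding RK refit, and the fitted activity coefficient of the
    shared component at the (experimental) eutectic point."""

    dHm_assumed: float  # J/mol
    fit: FitResult
    gamma_at_xe: float
    feasible: bool = True


def _collect_branch1_log_solubility(
    datasets: Sequence[SLEDataset],
) -> tuple[np.ndarray, np.ndarray]:
    xs, Ts = [], []
    for ds in datasets:
        for p in ds.points:
            if p.branch == 1 and 0.0 < p.x1 <= 1.0:
                xs.append(p.x1)
                Ts.append(p.T)
    return np.asarray(xs), np.asarray(Ts)


def _ols_line(u: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """OLS of v on u; returns (slope, intercept, r_squared)."""
    A = np.column_stack([u, np.ones_like(u)])
    (slope, intercept), *_ = np.linalg.lstsq(A, v, rcond=None)
    resid = v - (slope * u + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(v - v.mean(), v - v.mean()))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    # two points define the line exactly; ss_tot may be 0 only for duplicates
    if len(u) == 2:
        r2 = 1.0
    return float(slope), float(intercept), r2


def fit_ideal_melting_properties(
    datasets: SLEDataset | Sequence[SLEDataset], pooled: bool = True
) -> MeltingFit | list[MeltingFit]:
    """Back-fit the shared component's melting properties assuming ideal
    solubility.

    Regresses ln(x1) on 1/T over branch-1 points; the slope s and intercept
    c give dHm = -R s and Tm = -s/c (since c = dHm/(R Tm)). With
    ``pooled=True`` all datasets are concatenated into a single regression;
    otherwise one fit per dataset is returned.

    Raises
    ------
    DegenerateFitError
        With fewer than two distinct points, or a zero intercept (infinite
        melting temperature).
    """
    if isinstance(datasets, SLEDataset):
        datasets = [datasets]
    if not pooled:
        return [fit_ideal_melting_properties([ds], pooled=True) for ds in datasets]

    x, T = _collect_branch1_log_solubility(datasets)
    if len(np.unique(np.column_stack([x, T]), axis=0)) < 2:
        raise DegenerateFitError(
            f"need >= 2 distinct branch-1 points, got {len(x)}"
        )
    u = 1.0 / T
    v = np.log(x)
    slope, intercept, r2 = _ols_line(u, v)
    if intercept == 0.0:
        raise DegenerateFitError("zero intercept: melting temperature unidentified")
    dHm_hat = -R * slope
    Tm_hat = -slope / intercept
    return MeltingFit(
        dHm_hat=dHm_hat,
        Tm_hat=Tm_hat,
        r_squared=r2,
        slope=slope,
        intercept=intercept,
        n_points=len(x),
    )


def compute_aad(T_calc, T_exp) -> float:
    """Average absolute deviation (K) between calculated and experimental
    liquidus temperatures, paired elementwise."""
    T_calc = np.asarray(T_calc, dtype=float)
    T_exp = np.asarray(T_exp, dtype=float)
    if T_calc.shape != T_exp.shape:
        raise ValueError(f"length mismatch: {T_calc.shape} vs {T_exp.shape}")
    if T_calc.size == 0:
        raise ValueError("need at least one point")
    return float(np.mean(np.abs(T_calc - T_exp)))


def _branch_points(
    dataset: SLEDataset, branch: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interior points of one branch as (x_cryst, xj, T)."""
    pts = [p for p in dataset.points if p.branch == branch and 0.0 < p.x_crystallizing < 1.0]
    x = np.array([p.x_crystallizing for p in pts])
    T = np.array([p.T for p in pts])
    return x, 1.0 - x, T


def fit_rk_coefficients(
    dataset: SLEDataset,
    props: MeltingProperties,
    n_terms: int = 1,
    branch: int = 1,
) -> FitResult:
    """Fit ``n_terms`` Redlich-Kister coefficients to one liquidus branch by
    minimizing OF = sum (gamma_cal - gamma_exp)^2.

    gamma_exp comes from inverting the liquidus equation point by point under
    the given melting properties; gamma_cal = exp(P(xj)/(R T)) at each
    observed temperature. The optimizer is deterministic: a trust-region
    least-squares refinement started from both the closed-form linear
    solution in R*T*ln(gamma) space and from the ideal (all-zero) point, the
    better of the two wins.

    The returned AAD re-predicts the liquidus temperatures with the fitted
    coefficients; if any composition becomes infeasible under them the AAD is
    +inf and the result is flagged.
    """
    if not 1 <= n_terms <= 3:
        raise ThermoDomainError(f"n_terms must be 1..3, got {n_terms}")
    x, xj, T = _branch_points(dataset, branch)
    if len(x) < n_terms:
        raise DegenerateFitError(
            f"need >= {n_terms} interior branch-{branch} points, got {len(x)}"
        )
    gamma_exp = np.array(
        [
            gamma_from_sle_point(SLEPoint(x1=xi if branch == 1 else 1 - xi, T=Ti, branch=branch), props)
            for xi, Ti in zip(x, T)
        ]
    )

    powers = np.arange(2, 2 + n_terms)
    M = xj[:, None] ** powers[None, :]

    def gamma_cal(theta: np.ndarray) -> np.ndarray:
        return np.exp((M @ theta) / (R * T))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return gamma_cal(theta) - gamma_exp

    # closed-form seed: linear least squares in R*T*ln(gamma) space
    y = R * T * np.log(gamma_exp)
    theta_lin, *_ = np.linalg.lstsq(M, y, rcond=None)

    best = None
    for theta0 in (theta_lin, np.zeros(n_terms)):
        try:
            sol = least_squares(
                residuals, theta0, method="lm" if len(x) >= n_terms else "trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=10_000,
            )
        except Exception as exc:  # pragma: no cover - optimizer pathologies
            raise FitError(f"Redlich-Kister optimization failed: {exc}") from exc
        of = float(np.sum(sol.fun**2))
        if best is None or of < best[1]:
            best = (sol.x, of)
    theta, objective = best

    coeffs = RKCoefficients(tuple(theta))
    T_pred, numerator = _closed_form_liquidus(x, props, coeffs)
    feasible = bool(np.all(numerator > 0))
    aad = compute_aad(T_pred, T) if feasible else math.inf
    return FitResult(
        coeffs=coeffs,
        objective=objective,
        aad=aad,
        n_points=len(x),
        feasible=feasible,
    )


def _interp_eutectic_temperature(dataset: SLEDataset, x_eutectic: float) -> float:
    x, T = dataset.branch(1)
    if len(x) < 2:
        raise DegenerateFitError("need >= 2 branch-1 points to interpolate T at x_e")
    return float(np.interp(x_eutectic, x, T))


def screen_melting_enthalpy(
    dataset: SLEDataset,
    Tm_fixed: float,
    dHm_grid: Iterable[float],
    n_terms: int = 2,
    x_eutectic: float | None = None,
    T_eutectic: float | None = None,
) -> list[ScreeningRecord]:
    """Screen assumed melting enthalpies of Component 1 at fixed melting
    temperature.

    For each enthalpy on the grid, the experimental activity coefficients
    are recomputed under the shifted reference state, the Redlich-Kister
    coefficients are refitted, and the fitted gamma of Component 1 is
    evaluated at the eutectic point (x_eutectic, T_eutectic); when
    ``T_eutectic`` is omitted it is interpolated from the branch-1 data.
    Enthalpies whose refit produces an infeasible liquidus are recorded with
    ``feasible=False`` rather than dropped.
    """
    grid = [float(h) for h in dHm_grid]
    if not grid:
        raise ValueError("dHm_grid must be non-empty")
    if any(h <= 0 for h in grid):
        raise ThermoDomainError("assumed melting enthalpies must be > 0")
    if Tm_fixed <= 0:
        raise ThermoDomainError("Tm_fixed must be > 0")
    if x_eutectic is None:
        x_eutectic = float(min(p.x1 for p in dataset.points if p.branch == 1))
    if T_eutectic is None:
        T_eutectic = _interp_eutectic_temperature(dataset, x_eutectic)

    records: list[ScreeningRecord] = []
    for dHm in grid:
        props = MeltingProperties(Tm=Tm_fixed, dHm=dHm)
        try:
            fit = fit_rk_coefficients(dataset, props, n_terms=n_terms)
        except FitError:
            ideal = FitResult(
                coeffs=RKCoefficients.ideal(), objective=math.inf,
                aad=math.inf, n_points=0, feasible=False,
            )
            records.append(
                ScreeningRecord(dHm_assumed=dHm, fit=ideal, gamma_at_xe=math.nan, feasible=False)
            )
            continue
        gamma_xe = float(
            np.exp(fit.coeffs.excess(1.0 - x_eutectic) / (R * T_eutectic))
        )
        records.append(
            ScreeningRecord(
                dHm_assumed=dHm, fit=fit, gamma_at_xe=gamma_xe, feasible=fit.feasible
            )
        )
    return records


def screening_table(records: Sequence[ScreeningRecord]) -> pd.DataFrame:
    """Flatten screening records into the exported CSV layout."""
    rows = []
    for r in records:
        cs = r.fit.coeffs.coeffs
        rows.append(
            {
                "dHm_Jmol": r.dHm_assumed,
                "a": cs[0] if len(cs) > 0 else 0.0,
                "b": cs[1] if len(cs) > 1 else 0.0,
                "c": cs[2] if len(cs) > 2 else 0.0,
                "OF": r.fit.objective,
                "AAD_K": r.fit.aad,
                "gamma_at_xe": r.gamma_at_xe,
                "feasible": r.feasible,
            }
        )
    return pd.DataFrame(rows)
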