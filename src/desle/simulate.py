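"""Synthetic solid-liquid-equilibrium data with known ground truth.

Real liquidus datasets for DES constituents live scattered across the
literature; this module generates statistically similar stand-ins from a
fully specified forward model, so that every fitting and screening stage can
be exercised against a known truth. The generator draws compositions on each
branch's feasible range (bounded away from the eutectic to avoid branch
ambiguity), evaluates the exact liquidus temperature, and adds Gaussian
noise to the temperature — temperature being the measured quantity in
DSC-style SLE experiments.

A "shared-component family" layout mirrors the common experimental design
where one hard-to-characterize salt (e.g. choline chloride) is paired with
several partners, and its melting properties are back-fitted from the pooled
solubility data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import MeltingProperties, RKCoefficients, SLEPoint
from .errors import NoPhysicalLiquidusError, ThermoDomainError
from .fitting import SLEDataset
from .phase_diagram import BinarySystem, branch_temperatures, eutectic_point

__all__ = ["GeneratorSpec", "simulate_sle_dataset", "simulate_shared_component_family"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic binary SLE dataset.

    Compositions are drawn uniformly on each branch's range; by default
    branch 1 spans [x1_e + margin, x1_max] and branch 2 [x1_min, x1_e -
    margin], where x1_e is the true eutectic composition. The seed is
    mandatory: identical specs produce identical datasets.
    """

    system: BinarySystem
    seed: int
    n_per_branch: int = 15
    sigma_T: float = 0.0  # K
    branches: tuple[int, ...] = (1, 2)
    eutectic_margin: float = 0.02  # mole fraction kept clear of x1_e
    x1_max: float = 0.99  # upper end of the branch-1 range
    x1_min: float = 0.01  # lower end of the branch-2 range
    x1_range_branch1: tuple[float, float] | None = None
    x1_range_branch2: tuple[float, float] | None = None

    def __post_init__(self):
        if self.n_per_branch < 1:
            raise ValueError("n_per_branch must be >= 1")
        if self.sigma_T < 0:
            raise ValueError("sigma_T must be >= 0")
        if not self.branches or any(b not in (1, 2) for b in self.branches):
            raise ValueError("branches must be a non-empty subset of (1, 2)")


def _branch_range(spec: GeneratorSpec, branch: int, x1_e: float) -> tuple[float, float]:
    explicit = spec.x1_range_branch1 if branch == 1 else spec.x1_range_branch2
    if explicit is not None:
        return explicit
    if branch == 1:
        return (min(x1_e + spec.eutectic_margin, spec.x1_max), spec.x1_max)
    return (spec.x1_min, max(x1_e - spec.eutectic_margin, spec.x1_min))


def simulate_sle_dataset(spec: GeneratorSpec) -> SLEDataset:
    """Draw one synthetic liquidus dataset from the spec's forward model.

    Raises
    ------
    NoPhysicalLiquidusError
        If the forward model is infeasible at any requested composition
        (the message lists the offending compositions).
    """
    rng = np.random.default_rng(spec.seed)
    eut = eutectic_point(spec.system)
    points: list[SLEPoint] = []
    for branch in spec.branches:
        lo, hi = _branch_range(spec, branch, eut.x1_e)
        if not lo < hi:
            raise ValueError(
                f"empty composition range for branch {branch}: [{lo:.4g}, {hi:.4g}]"
            )
        x1 = np.sort(rng.uniform(lo, hi, size=spec.n_per_branch))
        T = branch_temperatures(spec.system, branch, x1)
        bad = ~np.isfinite(T)
        if bad.any():
            raise NoPhysicalLiquidusError(
                float(x1[bad][0]),
                float("nan"),
            )
        T = T + rng.normal(0.0, spec.sigma_T, size=spec.n_per_branch) if spec.sigma_T else T
        points.extend(
            SLEPoint(x1=float(xi), T=float(Ti), branch=branch)
            for xi, Ti in zip(x1, T)
        )
    return SLEDataset(
        points=tuple(points),
        name1=spec.system.name1,
        name2=spec.system.name2,
        note=f"synthetic; seed={spec.seed}; sigma_T={spec.sigma_T} K",
    )


def simulate_shared_component_family(
    shared_props: MeltingProperties,
    partners: Sequence[tuple[MeltingProperties, RKCoefficients]],
    n_per_branch: int = 15,
    sigma_T: float = 0.0,
    seed: int = 0,
    shared_name: str = "shared",
    **spec_kwargs,
) -> list[SLEDataset]:
    """Generate one dataset per partner, all sharing Component 1.

    Each partner entry is (partner melting properties, branch-1 RK
    coefficients); branch 2 is left ideal. Per-partner seeds are spawned
    deterministically from ``seed``, so the family is reproducible as a
    whole.
    """
    if not partners:
        raise ValueError("need at least one partner")
    child_seeds = np.random.SeedSequence(seed).spawn(len(partners))
    datasets = []
    for k, ((props2, coeffs1), ss) in enumerate(zip(partners, child_seeds)):
        if props2.Tm > shared_props.Tm:
            raise ThermoDomainError(
                f"partner {k} melts above the shared component "
                f"({props2.Tm} K > {shared_props.Tm} K)"
            )
        system = BinarySystem(
            props1=shared_props,
            props2=props2,
            coeffs1=coeffs1,
            name1=shared_name,
            name2=f"partner-{k + 1}",
        )
        spec = GeneratorSpec(
            system=system,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            n_per_branch=n_per_branch,
            sigma_T=sigma_T,
            **spec_kwargs,
        )
        datasets.append(simulate_sle_dataset(spec))
    return datasets
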