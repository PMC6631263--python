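"""Parameter sweeps over melting properties and non-ideality.

The sweep engine maps grids of melting temperatures / enthalpies (linked by
a per-component melting-entropy convention) and single-parameter
Redlich-Kister coefficients onto eutectic-point properties, producing one
tidy record per grid node: (x1_e, Te, normalized depression, feasibility).

Two canonical studies are provided:

* the *ideal* sweep — gamma = 1 everywhere; isolates the effect of melting
  properties. At fixed melting entropy the normalized depression depends
  only on the Tm1/Tm2 ratio, and low melting enthalpies (low entropies)
  deepen the eutectic.
* the *non-ideality* sweep — melting temperatures pinned at 600 K / 300 K,
  four melting-enthalpy cases (each component's enthalpy from either the
  Walden entropy 54.4 or the low entropy 20.0 J/(mol K)), with one RK
  parameter per branch swept over [-30000, 0] J/mol.

Sweeps contain no randomness: rerunning a config reproduces the table
bit for bit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .constants import LOW_ENTROPY, WALDEN_ENTROPY, resolve_entropy
from .core import MeltingProperties, RKCoefficients
from .errors import NoEutecticError, NoPhysicalLiquidusError, ThermoDomainError
from .phase_diagram import BinarySystem, eutectic_point

__all__ = [
    "SweepConfig",
    "DEFAULT_A_GRID",
    "DEFAULT_TM_RATIO_GRID",
    "run_ideal_sweep",
    "run_nonideality_sweep",
]

#: Default single-parameter RK grid, J/mol (0 = ideal to -30 kJ/mol).
DEFAULT_A_GRID = (0.0, -6_000.0, -12_000.0, -18_000.0, -24_000.0, -30_000.0)

#: Default Tm1/Tm2 ratio grid for the ideal sweep.
DEFAULT_TM_RATIO_GRID = tuple(1.0 + 0.25 * k for k in range(9))  # 1.0 .. 3.0

#: The four melting-enthalpy cases of the non-ideality study:
#: each component's entropy is either Walden (54.4) or low (20.0) J/(mol K),
#: applied at Tm1 = 600 K / Tm2 = 300 K.
NONIDEAL_ENTHALPY_CASES = tuple(
    itertools.product((WALDEN_ENTROPY, LOW_ENTROPY), repeat=2)
)


@dataclass(frozen=True)
class SweepConfig:
    """Grid definition for a parameter sweep.

    For each component give either a melting-temperature grid (``tm*_grid``,
    K) or a melting-enthalpy grid (``dhm*_grid``, J/mol); the per-component
    entropy convention (``ds1`` / ``ds2``: 'walden', 'low', or a value in
    J/(mol K)) supplies the missing property via dHm = dSm * Tm.
    """

    mode: str = "ideal"  # 'ideal' | 'nonideal'
    tm1_grid: Sequence[float] | None = None
    tm2_grid: Sequence[float] | None = None
    dhm1_grid: Sequence[float] | None = None
    dhm2_grid: Sequence[float] | None = None
    ds1: float | str = "walden"
    ds2: float | str = "walden"
    a1_grid: Sequence[float] = field(default=(0.0,))
    a2_grid: Sequence[float] = field(default=(0.0,))

    def __post_init__(self):
        if self.mode not in ("ideal", "nonideal"):
            raise ValueError(f"mode must be 'ideal' or 'nonideal', got {self.mode!r}")
        for nm in ("tm1_grid", "tm2_grid", "dhm1_grid", "dhm2_grid", "a1_grid", "a2_grid"):
            g = getattr(self, nm)
            if g is not None and len(tuple(g)) == 0:
                raise ValueError(f"{nm} must be non-empty if given")
        for side in "12":
            if getattr(self, f"tm{side}_grid") is None and getattr(self, f"dhm{side}_grid") is None:
                raise ValueError(f"give tm{side}_grid or dhm{side}_grid")

    def component_nodes(self, side: int) -> list[tuple[float, float, float]]:
        """(Tm, dHm, dSm) nodes for one component."""
        ds = resolve_entropy(getattr(self, f"ds{side}"))
        tm_grid = getattr(self, f"tm{side}_grid")
        dhm_grid = getattr(self, f"dhm{side}_grid")
        nodes = []
        if tm_grid is not None:
            for tm in tm_grid:
                nodes.append((float(tm), ds * float(tm), ds))
        else:
            for dh in dhm_grid:
                nodes.append((float(dh) / ds, float(dh), ds))
        return nodes


def _solve_node(
    Tm1: float, dHm1: float, Tm2: float, dHm2: float, a1: float, a2: float
) -> dict:
    rec = {
        "Tm1_K": Tm1, "Tm2_K": Tm2,
        "dHm1_Jmol": dHm1, "dHm2_Jmol": dHm2,
        "a1_Jmol": a1, "a2_Jmol": a2,
        "x1_e": math.nan, "Te_K": math.nan, "norm_depression": math.nan,
        "feasible": False, "reason": "",
    }
    if Tm1 < Tm2:
        rec["reason"] = "tm_order"
        return rec
    try:
        system = BinarySystem(
            props1=MeltingProperties(Tm=Tm1, dHm=dHm1),
            props2=MeltingProperties(Tm=Tm2, dHm=dHm2),
            coeffs1=RKCoefficients((a1,) if a1 else ()),
            coeffs2=RKCoefficients((a2,) if a2 else ()),
        )
        eut = eutectic_point(system)
    except (NoEutecticError, NoPhysicalLiquidusError, ThermoDomainError) as exc:
        rec["reason"] = type(exc).__name__
        return rec
    rec.update(
        x1_e=eut.x1_e, Te_K=eut.Te, norm_depression=eut.norm_depression,
        feasible=True,
    )
    return rec


def run_ideal_sweep(config: SweepConfig | None = None) -> pd.DataFrame:
    """Sweep melting properties with gamma = 1 on both branches.

    The default configuration fixes Tm2 = 300 K, sweeps the Tm1/Tm2 ratio
    over 1.0–3.0, and runs both the Walden (54.4) and low (20.0 J/(mol K))
    entropy conventions applied to both components.
    """
    if config is None:
        frames = [
            run_ideal_sweep(
                SweepConfig(
                    mode="ideal",
                    tm1_grid=[300.0 * r for r in DEFAULT_TM_RATIO_GRID],
                    tm2_grid=[300.0],
                    ds1=ds, ds2=ds,
                )
            )
            for ds in (WALDEN_ENTROPY, LOW_ENTROPY)
        ]
        return pd.concat(frames, ignore_index=True)
    if config.mode != "ideal":
        raise ValueError("run_ideal_sweep requires mode='ideal'")
    rows = [
        _solve_node(Tm1, dH1, Tm2, dH2, 0.0, 0.0)
        for (Tm1, dH1, ds1) in config.component_nodes(1)
        for (Tm2, dH2, ds2) in config.component_nodes(2)
    ]
    df = pd.DataFrame(rows)
    df.insert(4, "dSm1", df["dHm1_Jmol"] / df["Tm1_K"])
    df.insert(5, "dSm2", df["dHm2_Jmol"] / df["Tm2_K"])
    return df


def run_nonideality_sweep(
    config: SweepConfig | None = None,
    Tm1: float = 600.0,
    Tm2: float = 300.0,
) -> pd.DataFrame:
    """Sweep single-parameter RK coefficients a1, a2 on both branches.

    Without a config, runs the four canonical melting-enthalpy cases
    (entropy 54.4 or 20.0 J/(mol K) per component at 600 K / 300 K) over the
    default a-grid on both branches. With a config, uses its grids
    (``dhm*_grid`` or ``tm*_grid`` + entropy conventions, and ``a*_grid``).
    """
    if config is None:
        rows = []
        for ds1, ds2 in NONIDEAL_ENTHALPY_CASES:
            for a1 in DEFAULT_A_GRID:
                for a2 in DEFAULT_A_GRID:
                    rows.append(
                        _solve_node(Tm1, ds1 * Tm1, Tm2, ds2 * Tm2, a1, a2)
                    )
        return pd.DataFrame(rows)
    if config.mode != "nonideal":
        raise ValueError("run_nonideality_sweep requires mode='nonideal'")
    rows = [
        _solve_node(Tm1_, dH1, Tm2_, dH2, float(a1), float(a2))
        for (Tm1_, dH1, _) in config.component_nodes(1)
        for (Tm2_, dH2, _) in config.component_nodes(2)
        for a1 in config.a1_grid
        for a2 in config.a2_grid
    ]
    return pd.DataFrame(rows)
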