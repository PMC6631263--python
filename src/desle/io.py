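"""Reading and writing SLE CSV tables, YAML configs, and run manifests.

The CSV dialect is: comma-separated, UTF-8, header required, columns
``x1`` (mole fraction of Component 1), ``T_K`` (liquidus temperature, K) and
``branch`` (1 or 2). Config files are YAML; enthalpy-like quantities may be
given either in J/mol (``*_Jmol`` keys) or kJ/mol (``*_kJmol`` keys), the
latter converted on read. All internal units are SI (J, mol, K).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from .core import MeltingProperties, RKCoefficients, SLEPoint
from .errors import SLEParseError, ThermoDomainError
from .fitting import SLEDataset
from .phase_diagram import BinarySystem

__all__ = [
    "read_sle_csv",
    "write_sle_csv",
    "read_config",
    "system_from_config",
    "melting_properties_from_config",
    "rk_from_config",
    "RunManifest",
]

REQUIRED_COLUMNS = ("x1", "T_K", "branch")

#: All floats written by the package use 10 significant digits.
FLOAT_FORMAT = "%.10g"


def read_sle_csv(path: str | Path) -> SLEDataset:
    """Parse an SLE CSV table into a validated dataset.

    Malformed rows are collected and reported together with their 1-based
    line numbers (the header is line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SLEParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SLEParseError(f"{path}: missing required column(s) {missing}")

    points: list[SLEPoint] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            x1, T, branch = float(row.x1), float(row.T_K), int(row.branch)
            points.append(SLEPoint(x1=x1, T=T, branch=branch))
        except (TypeError, ValueError, ThermoDomainError) as exc:
            bad.append((line, str(exc)))
    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad)
        raise SLEParseError(f"{path}: {len(bad)} malformed row(s): {detail}",
                            lines=[ln for ln, _ in bad])
    return SLEDataset(points=tuple(points), note=f"read from {path.name}")


def write_sle_csv(dataset: SLEDataset, path: str | Path) -> None:
    """Write a dataset in the same CSV dialect ``read_sle_csv`` accepts."""
    dataset.to_frame().to_csv(Path(path), index=False, float_format=FLOAT_FORMAT)


def read_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def _energy_from(cfg: dict, stem: str, default=None) -> float | None:
    """Read an energy-like value, accepting `<stem>_Jmol` or `<stem>_kJmol`."""
    if f"{stem}_Jmol" in cfg and f"{stem}_kJmol" in cfg:
        raise ValueError(f"give only one of {stem}_Jmol / {stem}_kJmol")
    if f"{stem}_Jmol" in cfg:
        return float(cfg[f"{stem}_Jmol"])
    if f"{stem}_kJmol" in cfg:
        return float(cfg[f"{stem}_kJmol"]) * 1000.0
    return default


def melting_properties_from_config(cfg: dict) -> MeltingProperties:
    """Build MeltingProperties from a mapping with keys Tm_K and dHm_Jmol
    (or dHm_kJmol), optional dCp_JmolK."""
    if "Tm_K" not in cfg:
        raise ValueError("melting-property config needs Tm_K")
    dHm = _energy_from(cfg, "dHm")
    if dHm is None:
        raise ValueError("melting-property config needs dHm_Jmol or dHm_kJmol")
    return MeltingProperties(
        Tm=float(cfg["Tm_K"]), dHm=dHm, dCp=float(cfg.get("dCp_JmolK", 0.0))
    )


def rk_from_config(cfg: dict, stem: str = "rk") -> RKCoefficients:
    """Read RK coefficients from `<stem>_Jmol` or `<stem>_kJmol` list keys."""
    if f"{stem}_Jmol" in cfg and f"{stem}_kJmol" in cfg:
        raise ValueError(f"give only one of {stem}_Jmol / {stem}_kJmol")
    if f"{stem}_Jmol" in cfg:
        return RKCoefficients(tuple(float(c) for c in cfg[f"{stem}_Jmol"]))
    if f"{stem}_kJmol" in cfg:
        return RKCoefficients(tuple(float(c) * 1000.0 for c in cfg[f"{stem}_kJmol"]))
    return RKCoefficients.ideal()


def system_from_config(cfg: dict) -> BinarySystem:
    """Build a BinarySystem from a config mapping.

    Expected layout::

        system:
          name1: salt          # optional labels
          name2: acid
          comp1: {Tm_K: 600, dHm_kJmol: 32.64}
          comp2: {Tm_K: 300, dHm_kJmol: 16.32}
          rk1_kJmol: [-30, 0]  # optional, default ideal
          rk2_kJmol: []
    """
    sys_cfg = cfg.get("system", cfg)
    for key in ("comp1", "comp2"):
        if key not in sys_cfg:
            raise ValueError(f"system config needs '{key}'")
    return BinarySystem(
        props1=melting_properties_from_config(sys_cfg["comp1"]),
        props2=melting_properties_from_config(sys_cfg["comp2"]),
        coeffs1=rk_from_config(sys_cfg, "rk1"),
        coeffs2=rk_from_config(sys_cfg, "rk2"),
        name1=str(sys_cfg.get("name1", "component-1")),
        name2=str(sys_cfg.get("name2", "component-2")),
    )


def _package_version() -> str:
    try:
        return version("desle")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted alongside every CLI artifact."""

    subcommand: str
    config_digest: str
    seed: int | None
    package_version: str
    created_utc: str

    @classmethod
    def create(cls, subcommand: str, config_payload, seed: int | None = None) -> "RunManifest":
        blob = json.dumps(config_payload, sort_keys=True, default=str).encode()
        return cls(
            subcommand=subcommand,
            config_digest=hashlib.sha256(blob).hexdigest(),
            seed=seed,
            package_version=_package_version(),
            created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def round_sig(value: float, digits: int = 10) -> float:
    """Round to a fixed number of significant digits for stable output."""
    return float(f"{value:.{digits}g}")
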