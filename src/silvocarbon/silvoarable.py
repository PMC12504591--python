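"""Per-hectare carbon stock of the *Coltura Promiscua* silvoarable system.

The historic system interplants three crops on the same hectare: rows of
mulberry trees, grapevines trained between the trees, and wheat in the
inter-rows. Its carbon stock (CS, t C ha^-1) follows the InVEST carbon-pool
convention — the sum of above-ground carbon (AGC), below-ground carbon
(BGC), dead matter (DM) and soil organic carbon (SOC) — with each pool
accumulated over the three crop components:

    CS = Σ_{c ∈ {tree, vine, wheat}} (AGC_c + BGC_c + DM_c + SOC_c)

Tree above-ground carbon uses a stem-volume allometry: stem volume is a
cylinder of breast-height diameter scaled by a form factor, converted to
biomass by wood density and to carbon by a carbon fraction,

    C_tree = cf · WD · f · (π/4) · DBH² · PH          [t C per tree]

with cf = 0.47 (IPCC default carbon fraction) and f = 0.5 (broadleaf form
factor). A power-law alternative AGB = a · DBH^b is selectable in
:class:`AllometryConfig`. Below-ground tree carbon is AGC times the
root-to-shoot ratio; vine carbon is per-vine biomass times vine density;
wheat carbon is standing biomass inferred from grain yield. Compartment
soil organic carbon (SOCt, SOCw, SOCv) enters the SOC pool directly as
per-hectare values.

All arithmetic broadcasts over NumPy arrays, so a parameter set of n
Monte-Carlo draws evaluates in one vectorised call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Union

import numpy as np

from .errors import DomainError

ArrayLike = Union[float, np.ndarray]

#: Model-input order used throughout the uncertainty machinery.
PARAM_NAMES: tuple[str, ...] = (
    "PH", "DBH", "RSt", "TA", "TD", "WD",
    "WY", "VD", "BioV", "SOCt", "SOCw", "SOCv",
)


@dataclass
class AllometryConfig:
    """Constants of the allometric and pool bookkeeping equations.

    form_factor
        Dimensionless stem form factor reducing the DBH-cylinder to stem
        volume; 0.5 is a conventional broadleaf value.
    carbon_fraction
        t C per t dry biomass; 0.47 per IPCC guidance.
    wheat_biomass_multiplier
        Total standing dry biomass per unit grain yield (dimensionless).
    dm_fraction
        Dead-matter pool as a fraction of tree AGC; 0 by default (no
        dead-matter datum for the historic system).
    stem_form
        "cylinder" (default, uses form_factor) or "power" for
        AGB = power_a · DBH^power_b t dry biomass per tree.
    soc_per_tree
        If True, SOCt is interpreted as per-tree soil carbon and scaled by
        tree density; the default treats SOCt/SOCw/SOCv as per-hectare
        compartment values summed directly into the SOC pool.
    """

    form_factor: float = 0.5
    carbon_fraction: float = 0.47
    wheat_biomass_multiplier: float = 1.0
    dm_fraction: float = 0.0
    stem_form: str = "cylinder"
    power_a: float = 0.1939
    power_b: float = 2.413
    soc_per_tree: bool = False

    def __post_init__(self) -> None:
        for name in ("form_factor", "carbon_fraction", "wheat_biomass_multiplier"):
            v = getattr(self, name)
            if not 0 < v <= 2:
                raise DomainError(f"{name} must lie in (0, 2], got {v}")
        if not 0 < self.carbon_fraction < 1:
            raise DomainError(f"carbon_fraction must lie in (0, 1), got {self.carbon_fraction}")
        if not 0 <= self.dm_fraction <= 2:
            raise DomainError(f"dm_fraction must lie in [0, 2], got {self.dm_fraction}")
        if self.stem_form not in ("cylinder", "power"):
            raise DomainError(f"unknown stem_form {self.stem_form!r}")


@dataclass
class BiophysicalParams:
    """The twelve inputs of the silvoarable carbon model.

    PH    mulberry plant height, m
    DBH   diameter at breast height, m
    RSt   root-to-shoot ratio, dimensionless (≤ 2)
    TA    auxiliary tree attribute (carried for completeness; inert in the
          default equations)
    TD    mulberry tree density, trees ha^-1
    WD    mulberry wood density, t m^-3
    WY    wheat grain yield, t ha^-1
    VD    grapevine density, vines ha^-1
    BioV  grapevine biomass, t per vine
    SOCt  soil organic carbon of the tree compartment, t C ha^-1
    SOCw  soil organic carbon of the wheat compartment, t C ha^-1
    SOCv  soil organic carbon of the vine compartment, t C ha^-1

    Every field accepts a scalar or an array of draws.
    """

    PH: ArrayLike = 0.0
    DBH: ArrayLike = 0.0
    RSt: ArrayLike = 0.0
    TA: ArrayLike = 0.0
    TD: ArrayLike = 0.0
    WD: ArrayLike = 0.0
    WY: ArrayLike = 0.0
    VD: ArrayLike = 0.0
    BioV: ArrayLike = 0.0
    SOCt: ArrayLike = 0.0
    SOCw: ArrayLike = 0.0
    SOCv: ArrayLike = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = np.asarray(getattr(self, f.name), dtype=float)
            if np.any(v < 0):
                raise DomainError(f"{f.name} must be non-negative")
        if np.any(np.asarray(self.RSt, dtype=float) > 2):
            raise DomainError("RSt above 2 is outside the plausible range")
        ph = np.asarray(self.PH, dtype=float)
        dbh = np.asarray(self.DBH, dtype=float)
        if np.any((ph > 0) & (dbh >= ph)):
            warnings.warn("DBH >= PH: numerically implausible tree geometry", stacklevel=2)

    @classmethod
    def from_dict(cls, values: dict[str, ArrayLike]) -> "BiophysicalParams":
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise DomainError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**values)  # type: ignore[arg-type]


@dataclass
class CarbonPools:
    """The four InVEST carbon pools, each in t C ha^-1."""

    AGC: ArrayLike = 0.0
    BGC: ArrayLike = 0.0
    DM: ArrayLike = 0.0
    SOC: ArrayLike = 0.0

    @property
    def total(self) -> ArrayLike:
        return self.AGC + self.BGC + self.DM + self.SOC

    def __add__(self, other: "CarbonPools") -> "CarbonPools":
        return CarbonPools(
            AGC=self.AGC + other.AGC,
            BGC=self.BGC + other.BGC,
            DM=self.DM + other.DM,
            SOC=self.SOC + other.SOC,
        )


@dataclass
class SilvoarableResult:
    """Total carbon stock with its component-by-pool breakdown."""

    tree: CarbonPools
    vine: CarbonPools
    wheat: CarbonPools

    @property
    def pools(self) -> CarbonPools:
        return self.tree + self.vine + self.wheat

    @property
    def total(self) -> ArrayLike:
        return self.pools.total


def tree_stem_carbon(
    DBH: ArrayLike,
    PH: ArrayLike,
    WD: ArrayLike,
    cfg: AllometryConfig | None = None,
) -> ArrayLike:
    """Carbon held in one mulberry stem, t C per tree."""
    cfg = cfg or AllometryConfig()
    DBH, PH, WD = (np.asarray(x, dtype=float) for x in (DBH, PH, WD))
    if np.any(DBH < 0) or np.any(PH < 0) or np.any(WD < 0):
        raise DomainError("DBH, PH and WD must be non-negative")
    if cfg.stem_form == "power":
        agb = cfg.power_a * DBH ** cfg.power_b
        out = cfg.carbon_fraction * agb
    else:
        volume = cfg.form_factor * (np.pi / 4.0) * DBH**2 * PH
        out = cfg.carbon_fraction * WD * volume
    return out if out.ndim else float(out)


def tree_component(p: BiophysicalParams, cfg: AllometryConfig | None = None) -> CarbonPools:
    """Per-hectare pools of the mulberry component."""
    cfg = cfg or AllometryConfig()
    agc = np.asarray(p.TD, dtype=float) * tree_stem_carbon(p.DBH, p.PH, p.WD, cfg)
    soc = np.asarray(p.SOCt, dtype=float)
    if cfg.soc_per_tree:
        soc = soc * np.asarray(p.TD, dtype=float)
    return CarbonPools(AGC=agc, BGC=agc * np.asarray(p.RSt, dtype=float),
                       DM=cfg.dm_fraction * agc, SOC=soc)


def vine_component(p: BiophysicalParams, cfg: AllometryConfig | None = None) -> CarbonPools:
    """Per-hectare pools of the grapevine component."""
    cfg = cfg or AllometryConfig()
    agc = cfg.carbon_fraction * np.asarray(p.VD, dtype=float) * np.asarray(p.BioV, dtype=float)
    return CarbonPools(AGC=agc, SOC=np.asarray(p.SOCv, dtype=float))


def wheat_component(p: BiophysicalParams, cfg: AllometryConfig | None = None) -> CarbonPools:
    """Per-hectare pools of the wheat component."""
    cfg = cfg or AllometryConfig()
    agc = cfg.carbon_fraction * cfg.wheat_biomass_multiplier * np.asarray(p.WY, dtype=float)
    return CarbonPools(AGC=agc, SOC=np.asarray(p.SOCw, dtype=float))


def silvoarable_cs(
    p: BiophysicalParams, cfg: AllometryConfig | None = None
) -> SilvoarableResult:
    """Total silvoarable carbon stock (t C ha^-1) with component breakdown.

    The total is the exact pool-wise sum of the tree, vine and wheat
    components; the function is pure and deterministic.
    """
    cfg = cfg or AllometryConfig()
    return SilvoarableResult(
        tree=tree_component(p, cfg),
        vine=vine_component(p, cfg),
        wheat=wheat_component(p, cfg),
    )


def breakdown_frame(result: SilvoarableResult):
    """Component × pool table of a scalar evaluation (for CSV export)."""
    import pandas as pd

    rows = []
    for name, pools in (("tree", result.tree), ("vine", result.vine),
                        ("wheat", result.wheat), ("total", result.pools)):
        rows.append({
            "component": name,
            "AGC": float(np.asarray(pools.AGC)),
            "BGC": float(np.asarray(pools.BGC)),
            "DM": float(np.asarray(pools.DM)),
            "SOC": float(np.asarray(pools.SOC)),
            "total": float(np.asarray(pools.total)),
        })
    return pd.DataFrame(rows)
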