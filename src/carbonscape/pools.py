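"""Per-class carbon-density pools (Mg/ha).

Four pools are tracked per land-cover class: above-ground carbon (CAG),
below-ground carbon (CBG), soil organic carbon (CSOIL) and dead-organic-
matter carbon (CDOM).

Forest pools are scaled from growing stock GS (m³/ha) via

    BAG  = GS · BEF · WBD          above-ground biomass, Mg d.m./ha
    CAG  = BAG · CF
    CBG  = BAG · R · CF            (R converts above- to below-ground)
    CDOM = CAG · AMR + litter_fraction · CAG

The below-ground relation uses the root-to-shoot ratio R explicitly; a
variant sometimes printed without R is a typo since R is defined exactly as
the factor converting above-ground to below-ground biomass.  Litter carbon
is regression-based in the source inventory literature with unpublished
coefficients, so it is exposed here as a configurable ``litter_fraction``
of CAG (default 0).

Grassland pools follow IPCC defaults (BAG = 2.7 Mg d.m./ha, root-to-shoot
4.0, carbon fraction 0.5); crop and wetland pools are unweighted means of
per-type tables.  The shipped :func:`default_pool_table` is the
authoritative assessment input for the Calabria study region; the
equation-based constructors are provided for methodology reuse and are not
forced to match it (e.g. the shipped Forest CAG of 93 Mg/ha is not
reproducible from the shipped mean scaling factors, which give 82.3).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .raster import ClassScheme

__all__ = [
    "POOL_FIELDS",
    "ForestScalingFactors",
    "CarbonPoolTable",
    "forest_pools",
    "grassland_pools",
    "mean_pools",
    "default_pool_table",
    "default_forest_factors",
    "crop_pool_rows",
    "wetland_pool_rows",
    "read_pool_table",
]

POOL_FIELDS = ("CAG", "CBG", "CSOIL", "CDOM")

#: growing stock of Calabrian forests from the national forest inventory, m³/ha
DEFAULT_GROWING_STOCK = 225.4


def _data(name: str):
    return resources.files("carbonscape.data").joinpath(name)


@dataclass(frozen=True)
class ForestScalingFactors:
    """Factors converting forest growing stock to carbon pools."""

    GS: float = DEFAULT_GROWING_STOCK  # m³/ha
    BEF: float = 1.34                  # biomass expansion factor
    WBD: float = 0.58                  # wood basic density, Mg d.m./m³
    CF: float = 0.47                   # carbon fraction, Mg C / Mg d.m.
    R: float = 0.25                    # root-to-shoot ratio
    AMR: float = 0.0177                # average mortality rate, 1/yr
    litter_fraction: float = 0.0       # litter carbon as a fraction of CAG

    def __post_init__(self) -> None:
        for name in ("GS", "BEF", "WBD", "litter_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("CF", "R", "AMR"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def forest_pools(f: ForestScalingFactors, soil_c: float) -> dict[str, float]:
    """Forest CAG/CBG/CSOIL/CDOM (Mg/ha) from growing stock and factors."""
    bag = f.GS * f.BEF * f.WBD
    cag = bag * f.CF
    cbg = bag * f.R * f.CF
    cdom = cag * f.AMR + f.litter_fraction * cag
    return {"CAG": cag, "CBG": cbg, "CSOIL": float(soil_c), "CDOM": cdom}


def grassland_pools(
    bag: float = 2.7, rts: float = 4.0, cf: float = 0.5, soil_c: float = 66.0
) -> dict[str, float]:
    """Grassland pools from the IPCC default above-ground biomass."""
    if min(bag, rts, cf, soil_c) < 0:
        raise ValueError("grassland pool inputs must be non-negative")
    return {"CAG": bag * cf, "CBG": bag * rts * cf, "CSOIL": float(soil_c), "CDOM": 0.0}


def mean_pools(rows: Sequence[dict[str, float]]) -> dict[str, float]:
    """Unweighted arithmetic mean of per-type pool rows, field by field."""
    if len(rows) == 0:
        raise ValueError("cannot average an empty list of pool rows")
    fields = rows[0].keys()
    for row in rows[1:]:
        if row.keys() != fields:
            raise ValueError("pool rows must have consistent fields")
    return {k: float(np.mean([row[k] for row in rows])) for k in fields}


@dataclass
class CarbonPoolTable:
    """CAG/CBG/CSOIL/CDOM densities (Mg/ha) for every class of a scheme."""

    scheme: ClassScheme
    densities: pd.DataFrame  # indexed by class code, columns POOL_FIELDS

    def __post_init__(self) -> None:
        df = self.densities
        missing_cols = [c for c in POOL_FIELDS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"pool table missing columns {missing_cols}")
        missing = [c for c in self.scheme.codes if c not in df.index]
        extra = [c for c in df.index if c not in self.scheme.codes]
        if missing or extra:
            raise ValueError(
                f"pool classes must exactly match the scheme; missing {missing}, extra {extra}"
            )
        if (df[list(POOL_FIELDS)] < 0).any().any():
            raise ValueError("pool densities must be non-negative")
        self.densities = df.loc[list(self.scheme.codes), list(POOL_FIELDS)].astype(float)

    def total_density(self) -> pd.Series:
        """CAG+CBG+CSOIL+CDOM per class, Mg/ha, in scheme order."""
        return self.densities.sum(axis=1)

    def row(self, code: int) -> dict[str, float]:
        return self.densities.loc[code].to_dict()

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.densities.copy()
        out.insert(0, "class_name", [self.scheme.name_of(c) for c in out.index])
        out.index.name = "class_code"
        out.to_csv(path)
        return path


def read_pool_table(path: str | Path, scheme: ClassScheme) -> CarbonPoolTable:
    df = pd.read_csv(path).set_index("class_code")
    return CarbonPoolTable(scheme, df)


def default_pool_table() -> CarbonPoolTable:
    """The shipped 7-class pool table for Calabria (Mg/ha)."""
    from .reclass import ipcc7_scheme

    df = pd.read_csv(_data("pool_table.csv")).set_index("class_code")
    return CarbonPoolTable(ipcc7_scheme(), df)


def default_forest_factors() -> pd.DataFrame:
    """Per-species forest scaling factors with their mean row."""
    return pd.read_csv(_data("forest_factors.csv")).set_index("tree_type")


def crop_pool_rows() -> list[dict[str, float]]:
    """Per-crop CAG/CBG rows (Mg/ha) for the woody crops of the region."""
    df = pd.read_csv(_data("crop_pools.csv"))
    return [{"CAG": r.CAG, "CBG": r.CBG} for r in df.itertuples()]


def wetland_pool_rows() -> list[dict[str, float]]:
    """Per-wetland-type pool rows (Mg/ha)."""
    df = pd.read_csv(_data("wetland_pools.csv"))
    return [
        {"CAG": r.CAG, "CBG": r.CBG, "CSOIL": r.CSOIL, "CDOM": r.CDOM}
        for r in df.itertuples()
    ]
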