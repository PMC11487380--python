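"""Carbon storage, sequestration, CO₂ equivalence and economic valuation.

Storage of a cell of area A hectares carrying class l is
``A · (CAG_l + CBG_l + CSOIL_l + CDOM_l)`` (Mg C); the map total is the sum
over non-nodata cells, identical (to rounding of nothing — both routes are
exact sums) to the class-aggregate route ``Σ area_km2 · 100 · density``.
Sequestration between two assessment years is the signed difference
``S = C_T2 − C_T1``; its CO₂ equivalent uses the molecular-weight ratio
44/12 exactly.

The economic value of a sequestration amount s over the period p→q applies
an annual market discount rate r (%) and an annual carbon-price change
c (%):

    value = V · s / (q − p) · Σ_{t=0}^{q-p-1} [(1 + r/100)(1 + c/100)]^{-t}

with V the carbon price (EUR/Mg C).  The multi-year ledger also reports the
undiscounted V·s for each period, since published period values in this
domain are sometimes quoted without the discount factor; stored-carbon
values are priced undiscounted (stored · V).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pools import CarbonPoolTable
from .raster import AreaTable, CategoricalRaster, area_table

__all__ = [
    "CO2_PER_C",
    "ValuationParams",
    "CarbonLedger",
    "carbon_map",
    "total_storage",
    "storage_from_areas",
    "sequestration",
    "co2_equivalent",
    "valuation",
    "stored_value",
    "build_ledger",
]

#: Mg CO₂ per Mg C (molecular weights 44 and 12)
CO2_PER_C = 44.0 / 12.0


@dataclass(frozen=True)
class ValuationParams:
    """Carbon price and discounting settings.

    V : carbon price, EUR per Mg C (default 200)
    r : annual market discount rate, percent (default 3)
    c : annual rate of change of the carbon price, percent (default 0)
    p, q : present and future year of the period being valued
    """

    V: float = 200.0
    r: float = 3.0
    c: float = 0.0
    p: int = 0
    q: int = 1

    def __post_init__(self) -> None:
        if self.V < 0:
            raise ValueError("carbon price V must be non-negative")
        if self.q <= self.p:
            raise ValueError(f"future year q={self.q} must exceed present year p={self.p}")


def carbon_map(r: CategoricalRaster, pools: CarbonPoolTable) -> np.ndarray:
    """Per-cell carbon storage (Mg C): A_ha × total pool density of the class.

    Returns a float array with NaN at nodata cells.
    """
    missing = [c for c in set(np.unique(r.grid[r.valid_mask])) if c not in pools.scheme]
    if missing:
        raise ValueError(f"classes missing from the pool table: {sorted(missing)}")
    density = pools.total_density()
    out = np.full(r.shape, np.nan)
    for code in r.scheme.codes:
        out[r.grid == code] = r.cell_area_ha * density[code]
    return out


def total_storage(cm: np.ndarray) -> float:
    """Total stored carbon (Mg C): sum over non-nodata (non-NaN) cells."""
    return float(np.nansum(cm))


def storage_from_areas(a: AreaTable, pools: CarbonPoolTable) -> float:
    """Class-aggregate storage: Σ area_km2 · 100 · (CAG+CBG+CSOIL+CDOM)."""
    if a.scheme.codes != pools.scheme.codes:
        raise ValueError("area table and pool table must share the class scheme")
    density = pools.total_density().to_numpy()
    return float((a.area_km2 * 100.0 * density).sum())


def sequestration(ct1: float, ct2: float) -> float:
    """Signed carbon change C_T2 − C_T1 (Mg C); positive = sequestered."""
    return ct2 - ct1


def co2_equivalent(s: float) -> float:
    """Convert Mg C to Mg CO₂ with the exact 44/12 factor."""
    return s * CO2_PER_C


def valuation(vp: ValuationParams, s: float) -> float:
    """Discounted value (EUR) of an amount s (Mg C) sequestered over p→q."""
    years = vp.q - vp.p
    factor = (1 + vp.r / 100.0) * (1 + vp.c / 100.0)
    series = sum(factor**-t for t in range(years))
    return vp.V * s / years * series


def stored_value(stored: float, V: float = 200.0) -> float:
    """Value of a carbon stock in million EUR (stored · V / 1e6)."""
    return stored * V / 1e6


@dataclass
class CarbonLedger:
    """Multi-year carbon accounting: per-year stocks and per-period changes."""

    years: pd.DataFrame    # year, stored_Mg, stored_value_MEUR
    periods: pd.DataFrame  # year_from, year_to, variation_MgC, co2_eq_Mg,
                           # variation_value_MEUR (discounted), variation_value_undiscounted_MEUR

    def to_frame(self) -> pd.DataFrame:
        """Table-style layout: one row per year with trailing period columns."""
        out = self.years.copy()
        per = self.periods.set_index("year_to")
        for col in ("variation_MgC", "co2_eq_Mg", "variation_value_MEUR",
                    "variation_value_undiscounted_MEUR"):
            out[col] = [per[col].get(y, np.nan) for y in out["year"]]
        return out

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.6f")
        return path


def build_ledger(
    areas: Sequence[AreaTable],
    pools: CarbonPoolTable,
    vp: ValuationParams | None = None,
) -> CarbonLedger:
    """Assemble the stored-carbon / sequestration / valuation ledger.

    ``areas`` must carry strictly increasing integer year labels.  Each
    consecutive pair contributes a variation row valued both with the
    discounting formula (p, q = the pair's years) and undiscounted.
    """
    if len(areas) < 2:
        raise ValueError("a ledger needs at least two assessment years")
    vp = vp or ValuationParams()
    years = [int(a.year) for a in areas]
    if any(y2 <= y1 for y1, y2 in zip(years, years[1:])):
        raise ValueError(f"years must be strictly increasing, got {years}")

    stored = [storage_from_areas(a, pools) for a in areas]
    year_rows = pd.DataFrame(
        {
            "year": years,
            "stored_Mg": stored,
            "stored_value_MEUR": [stored_value(s, vp.V) for s in stored],
        }
    )
    period_rows = []
    for (y1, s1), (y2, s2) in zip(zip(years, stored), zip(years[1:], stored[1:])):
        s = sequestration(s1, s2)
        pvp = ValuationParams(V=vp.V, r=vp.r, c=vp.c, p=y1, q=y2)
        period_rows.append(
            {
                "year_from": y1,
                "year_to": y2,
                "variation_MgC": s,
                "co2_eq_Mg": co2_equivalent(s),
                "variation_value_MEUR": valuation(pvp, s) / 1e6,
                "variation_value_undiscounted_MEUR": vp.V * s / 1e6,
            }
        )
    return CarbonLedger(years=year_rows, periods=pd.DataFrame(period_rows))
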