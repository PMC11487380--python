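"""Reclassification of CORINE level-3 land cover to IPCC-style classes.

The 44 CORINE Land Cover (CLC) level-3 classes are merged into 7 broader
land-use categories — Settlement, Crop land, Forest land, Grassland,
Wetland, Water body, Other land — following IPCC land-category guidance with
water bodies kept separate from wetlands.  Source codes default to the CLC
raster grid codes 1–44 in standard level-3 order (CLC products are
distributed with either 3-digit codes or 1–44 grid codes; a legend file can
override the default).  Target codes are fixed 1–7 so transition matrices
and area tables are comparable across runs.

Note the standard CLC name "Bare rocks" corresponds to the category
sometimes labelled "Bare soil and rocks"; the shipped map uses standard
CLC names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .raster import CategoricalRaster, ClassScheme

__all__ = [
    "ReclassMap",
    "default_clc_map",
    "default_clc_scheme",
    "ipcc7_scheme",
    "reclassify",
    "read_reclass_map",
]

log = logging.getLogger(__name__)

#: the seven target classes, in fixed order (codes 1..7)
IPCC7_NAMES = (
    "Settlement",
    "Crop land",
    "Forest land",
    "Grassland",
    "Wetland",
    "Water body",
    "Other land",
)


def ipcc7_scheme() -> ClassScheme:
    """The 7-class target scheme (Settlement=1 … Other land=7)."""
    return ClassScheme(codes=tuple(range(1, 8)), names=IPCC7_NAMES)


@dataclass(frozen=True)
class ReclassMap:
    """A total map from source class codes to target class codes.

    ``policy`` controls what happens to raster codes absent from the map:
    ``"error"`` rejects the raster, ``"nodata"`` turns the cells into nodata
    (logging how many were affected).
    """

    entries: dict[int, int]
    target_scheme: ClassScheme
    policy: Literal["error", "nodata"] = "error"

    def __post_init__(self) -> None:
        for src, tgt in self.entries.items():
            if tgt not in self.target_scheme:
                raise ValueError(f"target code {tgt} (for source {src}) not in target scheme")

    @property
    def source_codes(self) -> tuple[int, ...]:
        return tuple(sorted(self.entries))


def _data_path(name: str):
    return resources.files("carbonscape.data").joinpath(name)


def read_reclass_map(
    path: str | Path,
    policy: Literal["error", "nodata"] = "error",
    target_scheme: ClassScheme | None = None,
) -> ReclassMap:
    """Read a reclass map from delimited text (source_code, ..., target_code)."""
    df = pd.read_csv(path)
    if target_scheme is None:
        if "target_name" in df:
            tgt = df[["target_code", "target_name"]].drop_duplicates().sort_values("target_code")
            target_scheme = ClassScheme(tuple(tgt["target_code"].astype(int)), tuple(tgt["target_name"]))
        else:
            codes = tuple(sorted(df["target_code"].astype(int).unique()))
            target_scheme = ClassScheme(codes, tuple(str(c) for c in codes))
    entries = dict(zip(df["source_code"].astype(int), df["target_code"].astype(int)))
    if len(entries) != len(df):
        raise ValueError(f"{path}: duplicate source codes in reclass map")
    return ReclassMap(entries, target_scheme, policy=policy)


def default_clc_map(policy: Literal["error", "nodata"] = "error") -> ReclassMap:
    """The shipped 44→7 CLC reclassification map."""
    with resources.as_file(_data_path("clc_reclass.csv")) as p:
        return read_reclass_map(p, policy=policy, target_scheme=ipcc7_scheme())


def default_clc_scheme() -> ClassScheme:
    """Source scheme of the shipped map: CLC grid codes 1–44 with names."""
    df = pd.read_csv(_data_path("clc_reclass.csv"))
    return ClassScheme(tuple(df["source_code"].astype(int)), tuple(df["source_name"]))


def reclassify(r: CategoricalRaster, m: ReclassMap) -> CategoricalRaster:
    """Cell-wise substitution of source codes by target codes.

    Nodata is preserved.  Unmapped codes are handled per ``m.policy``.
    """
    lut_src = np.array(sorted(m.entries), dtype=np.int32)
    lut_tgt = np.array([m.entries[s] for s in sorted(m.entries)], dtype=np.int32)

    grid = r.grid
    valid = r.valid_mask
    idx = np.searchsorted(lut_src, grid)
    idx_clipped = np.clip(idx, 0, len(lut_src) - 1)
    mapped = lut_src[idx_clipped] == grid
    unmapped = valid & ~mapped
    if unmapped.any():
        codes, counts = np.unique(grid[unmapped], return_counts=True)
        detail = ", ".join(f"{int(c)} ({int(n)} cells)" for c, n in zip(codes, counts))
        if m.policy == "error":
            raise ValueError(f"unmapped source codes: {detail}")
        log.warning("reclassify: %d cells with unmapped codes set to nodata: %s",
                    int(unmapped.sum()), detail)

    out = np.full(grid.shape, r.nodata_code, dtype=np.int32)
    ok = valid & mapped
    out[ok] = lut_tgt[idx_clipped[ok]]
    return CategoricalRaster(
        out,
        m.target_scheme,
        cell_size_m=r.cell_size_m,
        origin=r.origin,
        nodata_code=r.nodata_code,
        crs_tag=r.crs_tag,
    )
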