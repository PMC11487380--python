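"""Categorical raster data model and I/O.

A :class:`CategoricalRaster` is the common currency of every spatial stage:
an integer class grid with a square cell size, a nodata code, an upper-left
origin and an opaque CRS tag.  Rasters are stored row-major with the row
index increasing southward (the usual GeoTIFF convention); all indices are
0-based.  Two on-disk formats are supported: ESRI ASCII grid (``.asc``,
human-readable, used for test fixtures) and single-band integer TIFF
(``.tif``/``.tiff``) with georeference carried in a small JSON sidecar.

Nodata is propagated, never imputed: every downstream operation excludes
nodata cells from counts and totals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ClassScheme",
    "CategoricalRaster",
    "AreaTable",
    "read_raster",
    "write_raster",
    "clip_to_mask",
    "area_table",
    "DEFAULT_NODATA",
]

DEFAULT_NODATA = -9999

#: suffix of the JSON sidecar that carries georeference for TIFF rasters
TIFF_SIDECAR_SUFFIX = ".aux.json"


@dataclass(frozen=True)
class ClassScheme:
    """An ordered legend of integer class codes with one label per code."""

    codes: tuple[int, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        codes = tuple(int(c) for c in self.codes)
        names = tuple(str(n) for n in self.names)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "names", names)
        if len(codes) < 1:
            raise ValueError("a class scheme needs at least one code")
        if len(set(codes)) != len(codes):
            raise ValueError(f"class codes must be distinct, got {codes}")
        if len(names) != len(codes):
            raise ValueError("need exactly one name per code")

    @property
    def J(self) -> int:
        """Number of classes."""
        return len(self.codes)

    def index_of(self, code: int) -> int:
        return self.codes.index(code)

    def name_of(self, code: int) -> str:
        return self.names[self.index_of(code)]

    def __contains__(self, code: object) -> bool:
        return code in self.codes


@dataclass
class CategoricalRaster:
    """Integer class grid with cell size, nodata and georeference tag.

    Parameters
    ----------
    grid
        2-D integer array of class codes (row-major, origin upper-left).
    scheme
        Legend the non-nodata codes must belong to.
    cell_size_m
        Side of the (square) cell in metres.
    origin
        ``(x, y)`` map coordinates of the upper-left corner.
    nodata_code
        Code marking cells outside the area of interest.
    crs_tag
        Opaque coordinate-reference identifier; compared verbatim.
    """

    grid: np.ndarray
    scheme: ClassScheme
    cell_size_m: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_code: int = DEFAULT_NODATA
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError(f"grid must be integer, got dtype {self.grid.dtype}")
        self.grid = self.grid.astype(np.int32, copy=False)
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if int(self.nodata_code) in self.scheme:
            raise ValueError("nodata code collides with a scheme code")
        self.validate_codes()

    # -- validity ----------------------------------------------------------

    def validate_codes(self) -> None:
        """Raise if any non-nodata cell carries a code outside the scheme."""
        bad = self._foreign_codes()
        if bad:
            detail = ", ".join(f"code {c}: {n} cells" for c, n in sorted(bad.items()))
            raise ValueError(f"codes outside scheme {self.scheme.codes}: {detail}")

    def _foreign_codes(self) -> dict[int, int]:
        values, counts = np.unique(self.grid, return_counts=True)
        return {
            int(v): int(n)
            for v, n in zip(values, counts)
            if int(v) != self.nodata_code and int(v) not in self.scheme
        }

    # -- derived quantities ------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares (A = cell_size² / 10 000)."""
        return self.cell_size_m**2 / 1e4

    @property
    def valid_mask(self) -> np.ndarray:
        return self.grid != self.nodata_code

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def class_counts(self) -> np.ndarray:
        """Cell count per scheme class, in scheme order; nodata excluded."""
        counts = np.zeros(self.scheme.J, dtype=np.int64)
        values, n = np.unique(self.grid[self.valid_mask], return_counts=True)
        for v, k in zip(values, n):
            counts[self.scheme.index_of(int(v))] = k
        return counts

    def aligned_with(self, other: "CategoricalRaster") -> bool:
        """Same shape, cell size, origin and CRS tag."""
        return (
            self.shape == other.shape
            and self.cell_size_m == other.cell_size_m
            and self.origin == other.origin
            and self.crs_tag == other.crs_tag
        )

    def require_aligned(self, other: "CategoricalRaster", what: str = "rasters") -> None:
        if not self.aligned_with(other):
            raise ValueError(
                f"misaligned {what}: {self.shape}/{self.cell_size_m}/{self.origin}"
                f"/{self.crs_tag!r} vs {other.shape}/{other.cell_size_m}"
                f"/{other.origin}/{other.crs_tag!r}"
            )

    def with_grid(self, grid: np.ndarray, scheme: ClassScheme | None = None) -> "CategoricalRaster":
        """Copy of this raster with a new grid (and optionally a new scheme)."""
        return replace(self, grid=grid, scheme=scheme or self.scheme)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_raster(path: str | Path, scheme: ClassScheme) -> CategoricalRaster:
    """Read a categorical raster from an ESRI ASCII grid or single-band TIFF.

    Codes outside ``scheme`` (other than nodata) are rejected with a message
    listing each offending code and its cell count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        return _read_ascii_grid(path, scheme)
    if suffix in (".tif", ".tiff"):
        return _read_tiff(path, scheme)
    raise ValueError(f"unsupported raster format {suffix!r} (use .asc or .tif)")


def write_raster(r: CategoricalRaster, path: str | Path) -> Path:
    """Write a raster to ``.asc`` or ``.tif`` (+ JSON georeference sidecar)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        _write_ascii_grid(r, path)
    elif suffix in (".tif", ".tiff"):
        _write_tiff(r, path)
    else:
        raise ValueError(f"unsupported raster format {suffix!r} (use .asc or .tif)")
    return path


def _read_ascii_grid(path: Path, scheme: ClassScheme) -> CategoricalRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field {key!r}")
    body = "".join(lines[n_header:])
    values = np.array(body.split(), dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.size != nrows * ncols:
        raise ValueError(f"{path}: expected {nrows * ncols} cells, found {values.size}")
    if not np.all(values == np.round(values)):
        raise ValueError(f"{path}: non-integer cell values in categorical raster")
    grid = values.astype(np.int32).reshape(nrows, ncols)
    cell = header["cellsize"]
    # ESRI headers give the lower-left corner; convert to upper-left origin
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    nodata = int(header.get("nodata_value", DEFAULT_NODATA))
    return CategoricalRaster(grid, scheme, cell_size_m=cell, origin=origin, nodata_code=nodata)


def _write_ascii_grid(r: CategoricalRaster, path: Path) -> None:
    nrows, ncols = r.shape
    xll = r.origin[0]
    yll = r.origin[1] - nrows * r.cell_size_m
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {r.cell_size_m:.6f}\n")
        fh.write(f"nodata_value {r.nodata_code}\n")
        np.savetxt(fh, r.grid, fmt="%d")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + TIFF_SIDECAR_SUFFIX)


def _read_tiff(path: Path, scheme: ClassScheme) -> CategoricalRaster:
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path}: expected an integer band, got dtype {data.dtype}")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return CategoricalRaster(
        data.astype(np.int32),
        scheme,
        cell_size_m=float(meta.get("cell_size_m", 100.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        nodata_code=int(meta.get("nodata_code", DEFAULT_NODATA)),
        crs_tag=str(meta.get("crs_tag", "")),
    )


def _write_tiff(r: CategoricalRaster, path: Path) -> None:
    tifffile.imwrite(path, r.grid.astype(np.int32))
    meta = {
        "cell_size_m": r.cell_size_m,
        "origin": list(r.origin),
        "nodata_code": int(r.nodata_code),
        "crs_tag": r.crs_tag,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Spatial operations
# ---------------------------------------------------------------------------


def clip_to_mask(r: CategoricalRaster, mask: CategoricalRaster) -> CategoricalRaster:
    """Restrict a raster to a 0/1 mask: cells where mask == 0 become nodata.

    Idempotent; requires aligned rasters.
    """
    r.require_aligned(mask, "raster and mask")
    mask_values = mask.grid
    if not np.all(np.isin(mask_values, (0, 1))):
        raise ValueError("mask raster must contain only 0 and 1")
    out = np.where(mask_values == 1, r.grid, np.int32(r.nodata_code))
    return r.with_grid(out)


@dataclass
class AreaTable:
    """Per-class areas (km²) and fractions of the valid total for one year."""

    scheme: ClassScheme
    area_km2: np.ndarray
    fraction: np.ndarray
    year: str = ""

    def __post_init__(self) -> None:
        self.area_km2 = np.asarray(self.area_km2, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.area_km2.shape != (self.scheme.J,) or self.fraction.shape != (self.scheme.J,):
            raise ValueError("area and fraction vectors must have one entry per class")
        if np.any(self.area_km2 < 0):
            raise ValueError("areas must be non-negative")

    @classmethod
    def from_areas(cls, scheme: ClassScheme, area_km2: Sequence[float], year: str = "") -> "AreaTable":
        area = np.asarray(area_km2, dtype=float)
        total = area.sum()
        frac = area / total if total > 0 else np.zeros_like(area)
        return cls(scheme, area, frac, year=year)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year,
                "class_code": self.scheme.codes,
                "class_name": self.scheme.names,
                "area_km2": self.area_km2,
                "fraction": self.fraction,
            }
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def read(cls, path: str | Path, scheme: ClassScheme) -> "AreaTable":
        df = pd.read_csv(path)
        by_code = dict(zip(df["class_code"].astype(int), df["area_km2"].astype(float)))
        missing = [c for c in scheme.codes if c not in by_code]
        if missing:
            raise ValueError(f"{path}: missing class codes {missing}")
        year = str(df["year"].iloc[0]) if "year" in df and len(df) else ""
        return cls.from_areas(scheme, [by_code[c] for c in scheme.codes], year=year)


def area_table(r: CategoricalRaster, year: str = "") -> AreaTable:
    """Per-class area in km² and fraction of the non-nodata total.

    Classes absent from the raster report zero.  A raster with no valid cell
    has no denominator and is rejected.
    """
    counts = r.class_counts()
    total = counts.sum()
    if total == 0:
        raise ValueError("raster is entirely nodata: no area denominator")
    area_km2 = counts * r.cell_size_m**2 / 1e6
    fraction = counts / total
    return AreaTable(r.scheme, area_km2, fraction, year=year)
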