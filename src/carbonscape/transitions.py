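"""Transition-probability estimation by cross-tabulation of map pairs.

The probability that a cell moves from class *i* to class *j* over one
period is estimated by cross-tabulating two aligned land-cover maps and
row-normalising the count matrix.  Per-period matrices are combined into an
averaged matrix by an unweighted element-wise arithmetic mean, which keeps
rows stochastic exactly.  Rows for classes with no population at the start
of a period become identity rows (the class persists if it reappears), so
Chapman–Kolmogorov products stay defined.

Matrices are serialised at full precision; round only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .raster import CategoricalRaster, ClassScheme

__all__ = [
    "CrossTab",
    "TransitionMatrix",
    "cross_tabulate",
    "to_probabilities",
    "average_matrices",
    "read_matrix",
    "write_matrix",
    "default_transition_matrix",
]

ROW_SUM_TOL = 1e-9


@dataclass
class CrossTab:
    """J×J cell-count matrix: rows = class at time t, columns = time t+Δ."""

    counts: np.ndarray
    scheme: ClassScheme

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        J = self.scheme.J
        if self.counts.shape != (J, J):
            raise ValueError(f"counts must be {J}x{J}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64, copy=False)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.scheme.names, columns=self.scheme.names)


@dataclass
class TransitionMatrix:
    """Row-stochastic J×J matrix of class-change probabilities."""

    P: np.ndarray
    scheme: ClassScheme
    period: str = ""

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        J = self.scheme.J
        if self.P.shape != (J, J):
            raise ValueError(f"P must be {J}x{J}, got {self.P.shape}")
        if np.any(self.P < 0):
            raise ValueError("probabilities must be non-negative")
        rows = self.P.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=ROW_SUM_TOL, rtol=0):
            raise ValueError(f"rows must sum to 1 within {ROW_SUM_TOL}, got {rows}")

    @property
    def J(self) -> int:
        return self.scheme.J

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.scheme.names, columns=self.scheme.names)


def cross_tabulate(r1: CategoricalRaster, r2: CategoricalRaster) -> CrossTab:
    """Count joint class occurrences of two aligned same-scheme rasters.

    Cells that are nodata in either raster are excluded.
    """
    r1.require_aligned(r2)
    if r1.scheme != r2.scheme:
        raise ValueError("rasters must share a class scheme")
    J = r1.scheme.J
    valid = r1.valid_mask & r2.valid_mask
    code_to_idx = {c: k for k, c in enumerate(r1.scheme.codes)}
    lut = np.zeros(max(r1.scheme.codes) + 1, dtype=np.int64)
    for c, k in code_to_idx.items():
        lut[c] = k
    a = lut[r1.grid[valid]]
    b = lut[r2.grid[valid]]
    counts = np.bincount(a * J + b, minlength=J * J).reshape(J, J)
    return CrossTab(counts, r1.scheme)


def to_probabilities(c: CrossTab, period: str = "") -> TransitionMatrix:
    """Row-normalise a cross-tabulation; empty rows become identity rows."""
    counts = c.counts.astype(float)
    row_tot = counts.sum(axis=1)
    P = np.eye(c.scheme.J)
    populated = row_tot > 0
    P[populated] = counts[populated] / row_tot[populated, None]
    return TransitionMatrix(P, c.scheme, period=period)


def average_matrices(ms: Sequence[TransitionMatrix], period: str = "") -> TransitionMatrix:
    """Unweighted element-wise arithmetic mean of transition matrices."""
    if len(ms) == 0:
        raise ValueError("need at least one matrix to average")
    scheme = ms[0].scheme
    for m in ms[1:]:
        if m.scheme.J != scheme.J:
            raise ValueError("matrices must share dimensions")
    P = np.mean([m.P for m in ms], axis=0)
    return TransitionMatrix(P, scheme, period=period or " + ".join(m.period for m in ms))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_matrix(m: TransitionMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = m.to_frame()
    df.index.name = "class"
    df.to_csv(path, float_format="%.12g")
    return path


def read_matrix(path: str | Path, scheme: ClassScheme, period: str = "",
                normalise: bool = False) -> TransitionMatrix:
    """Read a matrix from delimited text with class-name header row/column.

    ``normalise=True`` rescales each row to sum exactly to 1, useful for
    published matrices rounded to few decimals (rows then sum to ≈1 only).
    """
    df = pd.read_csv(path, index_col=0)
    P = df.to_numpy(dtype=float)
    if normalise:
        P = P / P.sum(axis=1, keepdims=True)
    return TransitionMatrix(P, scheme, period=period)


def default_transition_matrix() -> TransitionMatrix:
    """The shipped 2000–2018 averaged 7-class matrix for Calabria.

    The published matrix is printed at 4 decimals, so its raw rows sum to 1
    only within ±1.5e-3; rows are renormalised here so the result is exactly
    stochastic.  Use :func:`raw_default_matrix_frame` for the verbatim table.
    """
    from .reclass import ipcc7_scheme

    path = resources.files("carbonscape.data").joinpath("avg_transition_matrix.csv")
    P = pd.read_csv(path, index_col=0).to_numpy(dtype=float)
    P = P / P.sum(axis=1, keepdims=True)
    return TransitionMatrix(P, ipcc7_scheme(), period="2000-2018 avg")


def raw_default_matrix_frame() -> pd.DataFrame:
    """The shipped averaged matrix exactly as published (4 dp, no renorm)."""
    path = resources.files("carbonscape.data").joinpath("avg_transition_matrix.csv")
    return pd.read_csv(path, index_col=0)
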