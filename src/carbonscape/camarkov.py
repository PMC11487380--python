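"""CA-Markov land-cover prediction.

A Markov chain sets the class-quantity targets (expected future counts
n'ᵀ = nᵀP, integer-rounded by largest remainder so the total is conserved),
and a cellular-automaton contiguity rule allocates those quantities
spatially.  The suitability of a cell for class *c* is

    suitability(cell, c) = P[current(cell), c] · (ε + f_c(cell))

where f_c is the fraction of class *c* in the filter_size×filter_size
neighbourhood (edge-truncated) and ε = 0.01 keeps transitions into locally
absent classes possible.  Quotas are interpolated linearly across the
configured number of CA iterations (one iteration per future year); the
full Markov step is applied once, not compounded per iteration.

Allocation within an iteration runs in two stages: persistence claims are
honoured first, in descending persistence suitability, up to each class's
quota; remaining cells are then relabelled greedily by descending
suitability under the remaining budgets.  This favours persistence exactly
as contiguity-based allocators do, and makes two invariants structural: an
identity matrix is a fixpoint, and an absorbing class never loses cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .raster import CategoricalRaster
from .transitions import TransitionMatrix

__all__ = [
    "PredictionConfig",
    "markov_quantities",
    "largest_remainder_round",
    "neighborhood_suitability",
    "predict",
]

#: suitability floor so locally absent classes can still be allocated
EPSILON = 0.01


@dataclass(frozen=True)
class PredictionConfig:
    """Settings of the CA allocation.

    filter_size : odd window side of the contiguity filter (default 5)
    iterations  : number of CA iterations (default 6, one per future year)
    seed        : RNG seed, used only with ``tie_break="random"``
    tie_break   : "deterministic" (suitability, persistence, row-major index)
                  or "random" (seeded shuffle among exact ties)
    """

    filter_size: int = 5
    iterations: int = 6
    seed: int = 0
    tie_break: Literal["deterministic", "random"] = "deterministic"

    def __post_init__(self) -> None:
        if self.filter_size < 3 or self.filter_size % 2 == 0:
            raise ValueError("filter_size must be an odd integer >= 3")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def largest_remainder_round(x: np.ndarray, total: int | None = None) -> np.ndarray:
    """Round non-negative reals to integers preserving their (integer) sum.

    Floors every entry, then distributes the remaining units to the largest
    fractional remainders (ties to the lowest index).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("cannot round negative quantities")
    if total is None:
        total = int(round(x.sum()))
    base = np.floor(x).astype(np.int64)
    short = total - int(base.sum())
    if short < 0:
        raise ValueError("total smaller than the sum of floors")
    if short > 0:
        remainders = x - base
        order = np.lexsort((np.arange(x.size), -remainders))
        base[order[:short]] += 1
    return base


def markov_quantities(counts: np.ndarray, P: TransitionMatrix) -> np.ndarray:
    """Expected future class counts nᵀP, integer-rounded conserving the total."""
    n = np.asarray(counts, dtype=float)
    if n.shape != (P.J,):
        raise ValueError(f"count vector must have length {P.J}")
    if np.any(n < 0):
        raise ValueError("counts must be non-negative")
    expected = n @ P.P
    return largest_remainder_round(expected, total=int(round(n.sum())))


def neighborhood_fractions(r: CategoricalRaster, filter_size: int) -> np.ndarray:
    """Per-class neighbourhood fraction surfaces, shape (J, rows, cols).

    Fractions are computed over the valid cells actually present in the
    edge-truncated window, so border cells use smaller windows and nodata
    cells never contribute.
    """
    size = (filter_size, filter_size)
    valid = r.valid_mask.astype(float)
    denom = ndimage.uniform_filter(valid, size=size, mode="constant", cval=0.0)
    out = np.zeros((r.scheme.J, *r.shape))
    with np.errstate(invalid="ignore", divide="ignore"):
        for k, code in enumerate(r.scheme.codes):
            onehot = (r.grid == code).astype(float)
            num = ndimage.uniform_filter(onehot, size=size, mode="constant", cval=0.0)
            frac = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
            out[k] = frac
    return out


def neighborhood_suitability(
    r: CategoricalRaster, P: TransitionMatrix, cfg: PredictionConfig
) -> np.ndarray:
    """Suitability surfaces, shape (J, rows, cols); nodata cells get 0."""
    if r.scheme != P.scheme:
        raise ValueError("raster and matrix must share a class scheme")
    frac = neighborhood_fractions(r, cfg.filter_size)
    valid = r.valid_mask
    # per-cell transition row: prow[c] at cell = P[current(cell), c]
    idx = np.zeros(r.shape, dtype=np.int64)
    for k, code in enumerate(r.scheme.codes):
        idx[r.grid == code] = k
    suit = np.zeros_like(frac)
    for c in range(r.scheme.J):
        suit[c] = P.P[idx, c] * (EPSILON + frac[c])
    suit *= valid
    return suit


def _allocate(
    current_idx: np.ndarray,
    suit: np.ndarray,
    quotas: np.ndarray,
    cfg: PredictionConfig,
) -> np.ndarray:
    """Assign each cell a class index meeting the quotas exactly.

    ``current_idx``: (n_cells,) current class index per valid cell;
    ``suit``: (J, n_cells) suitability; ``quotas``: (J,) target counts.
    """
    J, n = suit.shape
    if int(quotas.sum()) != n:
        raise RuntimeError("infeasible quotas: do not sum to the cell total")

    rng = np.random.default_rng(cfg.seed)
    if cfg.tie_break == "random":
        jitter_rank = rng.permutation(n)
    else:
        jitter_rank = np.arange(n)

    out = np.full(n, -1, dtype=np.int64)
    remaining = quotas.astype(np.int64).copy()

    # stage 1: persistence first — each class keeps its best-suited incumbents
    pers_suit = suit[current_idx, np.arange(n)]
    for c in range(J):
        mine = np.flatnonzero(current_idx == c)
        keep = min(len(mine), remaining[c])
        if keep > 0:
            order = np.lexsort((jitter_rank[mine], -pers_suit[mine]))
            kept = mine[order[:keep]]
            out[kept] = c
            remaining[c] -= keep

    # stage 2: greedy allocation of the displaced cells to open budgets
    free = np.flatnonzero(out < 0)
    if free.size:
        cand_cell = np.repeat(free, J)
        cand_cls = np.tile(np.arange(J), free.size)
        cand_suit = suit[cand_cls, cand_cell]
        persist = (current_idx[cand_cell] == cand_cls).astype(np.int8)
        order = np.lexsort((cand_cls, jitter_rank[cand_cell], -persist, -cand_suit))
        for k in order:
            cell = cand_cell[k]
            cls = cand_cls[k]
            if out[cell] < 0 and remaining[cls] > 0:
                out[cell] = cls
                remaining[cls] -= 1
        if np.any(out < 0):  # pragma: no cover - guarded by quota feasibility
            raise RuntimeError("allocation left cells unassigned")
    return out


def predict(
    r: CategoricalRaster, P: TransitionMatrix, cfg: PredictionConfig | None = None
) -> CategoricalRaster:
    """Predict a future raster from a current raster and a transition matrix.

    Runs ``cfg.iterations`` CA iterations; at iteration i the per-class
    quotas are the largest-remainder rounding of the linear interpolation
    between the current counts and the single-step Markov targets.  The
    output conserves the non-nodata cell total and meets the Markov targets
    exactly after the final iteration.
    """
    cfg = cfg or PredictionConfig()
    if r.scheme != P.scheme:
        raise ValueError("raster and matrix must share a class scheme")
    n0 = r.class_counts().astype(float)
    total = int(n0.sum())
    if total == 0:
        return r.with_grid(r.grid.copy())
    n_target = markov_quantities(n0, P).astype(float)

    current = r
    flat_valid = None
    for i in range(1, cfg.iterations + 1):
        frac_step = i / cfg.iterations
        quota = largest_remainder_round(n0 + (n_target - n0) * frac_step, total=total)
        suit = neighborhood_suitability(current, P, cfg)
        valid = current.valid_mask
        flat_valid = np.flatnonzero(valid.ravel())
        code_to_idx = {c: k for k, c in enumerate(r.scheme.codes)}
        cur_idx = np.array(
            [code_to_idx[int(v)] for v in current.grid.ravel()[flat_valid]], dtype=np.int64
        )
        suit_flat = suit.reshape(r.scheme.J, -1)[:, flat_valid]
        assigned = _allocate(cur_idx, suit_flat, quota, cfg)
        new_grid = np.full(r.grid.size, r.nodata_code, dtype=np.int32)
        codes = np.array(r.scheme.codes, dtype=np.int32)
        new_grid[flat_valid] = codes[assigned]
        current = r.with_grid(new_grid.reshape(r.shape))
    return current
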