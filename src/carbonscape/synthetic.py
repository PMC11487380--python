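"""Synthetic multi-year land-cover series with known Markov dynamics.

Stands in for a downloaded land-cover time series so the whole pipeline —
reclassification aside — runs and is testable offline.  The initial
landscape is a nearest-seed tessellation (guaranteeing every class is
present and a controllable patch count); subsequent years evolve each cell
by drawing from the row of a known row-stochastic transition matrix, with
an optional spatial-mixing term that re-weights the draw toward classes
present in the 3×3 neighbourhood so that change clusters the way land-cover
change does.

With ``spatial_mixing = 0`` the cells are independent Markov draws, so
cross-tabulating consecutive maps recovers the true matrix up to sampling
error — the estimation-consistency check of the transition estimator.

One integer seed drives a named pseudo-random stream per operation
(initial landscape, each evolution step), so sub-results are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import CategoricalRaster, ClassScheme
from .transitions import TransitionMatrix

__all__ = [
    "SyntheticConfig",
    "generate_initial",
    "evolve_markov",
    "generate_series",
    "default_synthetic_config",
]

_STREAMS = {"initial": 1, "evolve": 2}


def _rng(seed: int, stream: str, step: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed) % 2**31, _STREAMS[stream], step])


@dataclass
class SyntheticConfig:
    """Study-condition settings of the generator.

    Defaults emulate the shape of the real analysis: a 7-class landscape
    observed at 6-year steps whose dynamics follow the averaged Calabria
    transition matrix, on a 200×200 grid (the smallest size at which every
    class keeps a usable population across steps).
    """

    rows: int = 200
    cols: int = 200
    scheme: ClassScheme | None = None
    P_true: TransitionMatrix | None = None
    n_patch_seeds: int = 49
    n_steps: int = 3
    spatial_mixing: float = 0.25
    seed: int = 42
    start_year: int = 2000
    year_step: int = 6
    cell_size_m: float = 100.0

    def __post_init__(self) -> None:
        if self.scheme is None or self.P_true is None:
            from .reclass import ipcc7_scheme
            from .transitions import default_transition_matrix

            if self.scheme is None:
                self.scheme = ipcc7_scheme()
            if self.P_true is None:
                self.P_true = default_transition_matrix()
        if self.rows < 8 or self.cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.P_true.scheme.J != self.scheme.J:
            raise ValueError("P_true dimension must match the scheme")
        if self.n_patch_seeds < self.scheme.J:
            raise ValueError("need at least one patch seed per class")
        if not 0 <= self.spatial_mixing <= 1:
            raise ValueError("spatial_mixing must lie in [0, 1]")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")


def default_synthetic_config(**overrides) -> SyntheticConfig:
    return SyntheticConfig(**overrides)


def generate_initial(cfg: SyntheticConfig) -> CategoricalRaster:
    """Seeded-patch landscape: nearest-seed tessellation of random classes.

    The first J seeds get one class each (so every class is present); the
    rest draw classes uniformly.  Ties in distance resolve to the lowest
    class code.
    """
    rng = _rng(cfg.seed, "initial")
    J = cfg.scheme.J
    n = cfg.n_patch_seeds
    rr = rng.integers(0, cfg.rows, size=n)
    cc = rng.integers(0, cfg.cols, size=n)
    seed_cls = np.concatenate([
        rng.permutation(J),
        rng.integers(0, J, size=n - J),
    ])
    # squared distances from every cell to every seed; modest sizes only
    gr, gc = np.mgrid[0 : cfg.rows, 0 : cfg.cols]
    d2 = (gr[..., None] - rr) ** 2 + (gc[..., None] - cc) ** 2
    best = d2.min(axis=-1, keepdims=True)
    codes = np.array(cfg.scheme.codes)
    cand = np.where(d2 == best, codes[seed_cls], np.iinfo(np.int32).max)
    grid = cand.min(axis=-1).astype(np.int32)
    return CategoricalRaster(
        grid, cfg.scheme, cell_size_m=cfg.cell_size_m, crs_tag="synthetic"
    )


def evolve_markov(
    r: CategoricalRaster,
    P: TransitionMatrix,
    spatial_mixing: float = 0.0,
    seed: int = 0,
    step: int = 0,
) -> CategoricalRaster:
    """One Markov step: each cell draws its next class from P[current].

    With probability ``spatial_mixing`` a cell's row is first re-weighted by
    the set of classes present in its 3×3 neighbourhood (renormalised;
    rows with no neighbourhood support fall back to the plain row), which
    clusters transitions without changing which transitions are possible.
    """
    if r.scheme != P.scheme:
        raise ValueError("raster and matrix must share a class scheme")
    rng = _rng(seed, "evolve", step)
    J = r.scheme.J
    codes = np.array(r.scheme.codes, dtype=np.int32)
    valid = r.valid_mask
    idx = np.zeros(r.shape, dtype=np.int64)
    for k, code in enumerate(r.scheme.codes):
        idx[r.grid == code] = k

    rows = P.P[idx]  # (rows, cols, J)
    if spatial_mixing > 0:
        present = _neighbour_presence(r)  # (rows, cols, J) booleans
        weighted = rows * present
        norm = weighted.sum(axis=-1, keepdims=True)
        usable = norm[..., 0] > 0
        mix_draw = rng.random(r.shape) < spatial_mixing
        use_mix = (mix_draw & usable)[..., None]
        rows = np.where(use_mix, np.divide(weighted, np.maximum(norm, 1e-300)), rows)

    cdf = np.cumsum(rows, axis=-1)
    u = rng.random(r.shape)[..., None]
    new_idx = (u > cdf).sum(axis=-1).clip(0, J - 1)
    grid = np.where(valid, codes[new_idx], r.grid).astype(np.int32)
    return r.with_grid(grid)


def _neighbour_presence(r: CategoricalRaster) -> np.ndarray:
    """Boolean (rows, cols, J): is class k present in the 3×3 neighbourhood."""
    from scipy import ndimage

    out = np.zeros((*r.shape, r.scheme.J), dtype=bool)
    for k, code in enumerate(r.scheme.codes):
        onehot = (r.grid == code).astype(np.uint8)
        out[..., k] = ndimage.maximum_filter(onehot, size=3, mode="constant", cval=0) > 0
    return out


def generate_series(cfg: SyntheticConfig) -> list[tuple[str, CategoricalRaster]]:
    """Initial landscape plus ``n_steps`` evolutions, with year labels."""
    rasters = [generate_initial(cfg)]
    for step in range(cfg.n_steps):
        rasters.append(
            evolve_markov(
                rasters[-1],
                cfg.P_true,
                spatial_mixing=cfg.spatial_mixing,
                seed=cfg.seed,
                step=step,
            )
        )
    years = [str(cfg.start_year + i * cfg.year_step) for i in range(len(rasters))]
    return list(zip(years, rasters))
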