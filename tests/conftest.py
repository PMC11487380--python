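import numpy as np
import pytest

from carbonscape import CategoricalRaster, ClassScheme, ipcc7_scheme


@pytest.fixture
def scheme2() -> ClassScheme:
    return ClassScheme((1, 2), ("a", "b"))


@pytest.fixture
def scheme7() -> ClassScheme:
    return ipcc7_scheme()


@pytest.fixture
def make_raster():
    """Factory for small rasters with sensible defaults."""

    def _make(grid, scheme, cell_size_m=100.0, nodata=-9999, **kw):
        return CategoricalRaster(
            np.asarray(grid, dtype=np.int32),
            scheme,
            cell_size_m=cell_size_m,
            nodata_code=nodata,
            **kw,
        )

    return _make


@pytest.fixture
def random_pair(scheme7):
    """Pair of random aligned 7-class rasters for property-style checks."""

    def _make(seed, shape=(12, 15), nodata_frac=0.0):
        rng = np.random.default_rng(seed)
        grids = []
        for _ in range(2):
            g = rng.integers(1, 8, size=shape).astype(np.int32)
            if nodata_frac:
                mask = rng.random(shape) < nodata_frac
                g[mask] = -9999
            grids.append(g)
        return (
            CategoricalRaster(grids[0], scheme7),
            CategoricalRaster(grids[1], scheme7),
        )

    return _make


@pytest.fixture
def correlated_pair(scheme7):
    """Simulated/reference pair agreeing well above chance: the reference is
    the simulated map with a fraction of cells re-drawn, mimicking the regime
    of an actual prediction-vs-reference validation."""

    def _make(seed, shape=(15, 15), error_frac=0.1):
        rng = np.random.default_rng(seed)
        sim = rng.integers(1, 8, size=shape).astype(np.int32)
        ref = sim.copy()
        flip = rng.random(shape) < error_frac
        ref[flip] = rng.integers(1, 8, size=int(flip.sum()))
        return CategoricalRaster(sim, scheme7), CategoricalRaster(ref, scheme7)

    return _make
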