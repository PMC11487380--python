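import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from carbonscape import (
    ClassScheme,
    PredictionConfig,
    TransitionMatrix,
    markov_quantities,
    neighborhood_suitability,
    predict,
)
from carbonscape.camarkov import EPSILON, largest_remainder_round


class TestMarkovQuantities:
    def test_identity_matrix_leaves_counts_unchanged(self, scheme2):
        P = TransitionMatrix(np.eye(2), scheme2)
        np.testing.assert_array_equal(markov_quantities([10, 5], P), [10, 5])

    def test_direct_product(self, scheme2):
        P = TransitionMatrix([[0.9, 0.1], [0.0, 1.0]], scheme2)
        np.testing.assert_array_equal(markov_quantities([100, 0], P), [90, 10])

    @settings(deadline=None, max_examples=50)
    @given(
        counts=hnp.arrays(np.int64, (4,), elements=st.integers(0, 500)),
        raw=hnp.arrays(np.float64, (4, 4), elements=st.floats(0.01, 1.0)),
    )
    def test_total_always_conserved(self, counts, raw):
        scheme = ClassScheme((1, 2, 3, 4), tuple("abcd"))
        P = TransitionMatrix(raw / raw.sum(axis=1, keepdims=True), scheme)
        out = markov_quantities(counts, P)
        assert out.sum() == counts.sum()
        assert (out >= 0).all()

    def test_largest_remainder_ties_go_to_lowest_index(self):
        np.testing.assert_array_equal(largest_remainder_round([1.5, 1.5], total=3), [2, 1])


class TestSuitability:
    def test_uniform_raster_gives_spatially_constant_suitability(self, make_raster, scheme2):
        r = make_raster(np.ones((6, 6)), scheme2)
        P = TransitionMatrix([[0.8, 0.2], [0.3, 0.7]], scheme2)
        suit = neighborhood_suitability(r, P, PredictionConfig(filter_size=3))
        for c in range(2):
            assert np.ptp(suit[c]) == pytest.approx(0.0)

    def test_single_invader_neighbourhood_fractions(self, make_raster, scheme2):
        grid = np.ones((7, 7), dtype=int)
        grid[3, 3] = 2
        r = make_raster(grid, scheme2)
        P = TransitionMatrix([[0.5, 0.5], [0.5, 0.5]], scheme2)
        suit = neighborhood_suitability(r, P, PredictionConfig(filter_size=3))
        # cells adjacent to the invader see class-2 fraction 1/9
        assert suit[1][2, 2] == pytest.approx(0.5 * (EPSILON + 1 / 9))
        # distant cells see only the epsilon floor
        assert suit[1][0, 0] == pytest.approx(0.5 * EPSILON)

    def test_bounded_by_max_probability(self, random_pair):
        r, _ = random_pair(seed=3)
        rng = np.random.default_rng(0)
        raw = rng.random((7, 7))
        P = TransitionMatrix(raw / raw.sum(axis=1, keepdims=True), r.scheme)
        suit = neighborhood_suitability(r, P, PredictionConfig())
        assert suit.min() >= 0
        assert suit.max() <= P.P.max() * (1 + EPSILON)


class TestPredict:
    def test_identity_matrix_is_a_fixpoint(self, random_pair):
        r, _ = random_pair(seed=4)
        P = TransitionMatrix(np.eye(7), r.scheme)
        for iterations in (1, 6):
            out = predict(r, P, PredictionConfig(iterations=iterations))
            np.testing.assert_array_equal(out.grid, r.grid)

    def test_two_by_two_quota_arithmetic(self, make_raster, scheme2):
        r = make_raster(np.ones((2, 2)), scheme2)
        P = TransitionMatrix([[0.5, 0.5], [0.0, 1.0]], scheme2)
        out = predict(r, P, PredictionConfig(iterations=1, filter_size=3))
        assert (out.grid == 2).sum() == 2

    def test_seeded_runs_are_bit_identical(self, random_pair):
        r, _ = random_pair(seed=5, shape=(20, 20))
        rng = np.random.default_rng(1)
        raw = rng.random((7, 7)) + 5 * np.eye(7)
        P = TransitionMatrix(raw / raw.sum(axis=1, keepdims=True), r.scheme)
        cfg = PredictionConfig(seed=11, tie_break="random")
        np.testing.assert_array_equal(predict(r, P, cfg).grid, predict(r, P, cfg).grid)

    def test_output_counts_equal_markov_targets_exactly(self, random_pair):
        r, _ = random_pair(seed=6, shape=(25, 25))
        rng = np.random.default_rng(2)
        raw = rng.random((7, 7)) + 10 * np.eye(7)
        P = TransitionMatrix(raw / raw.sum(axis=1, keepdims=True), r.scheme)
        out = predict(r, P, PredictionConfig())
        np.testing.assert_array_equal(out.class_counts(), markov_quantities(r.class_counts(), P))

    def test_absorbing_class_never_loses_cells(self, make_raster, scheme2):
        rng = np.random.default_rng(7)
        r = make_raster(rng.integers(1, 3, size=(15, 15)), scheme2)
        P = TransitionMatrix([[0.7, 0.3], [0.0, 1.0]], scheme2)  # class 2 absorbing
        before = (r.grid == 2)
        out = predict(r, P, PredictionConfig(iterations=3, filter_size=3))
        assert (out.grid[before] == 2).all()

    def test_nodata_cells_stay_nodata_and_total_conserved(self, make_raster, scheme2):
        grid = np.ones((10, 10), dtype=int)
        grid[0, :] = -9999
        grid[5:, 5:] = 2
        r = make_raster(grid, scheme2)
        P = TransitionMatrix([[0.8, 0.2], [0.1, 0.9]], scheme2)
        out = predict(r, P, PredictionConfig(iterations=2, filter_size=3))
        assert (out.grid[0, :] == -9999).all()
        assert out.n_valid == r.n_valid

    def test_contiguity_filter_clusters_growth(self, make_raster, scheme2):
        """Allocated change must be at least as clustered as a random relabeling."""

        def same_class_neighbour_fraction(grid):
            same = 0
            pairs = 0
            for axis in (0, 1):
                a = np.take(grid, range(grid.shape[axis] - 1), axis=axis)
                b = np.take(grid, range(1, grid.shape[axis]), axis=axis)
                same += (a == b).sum()
                pairs += a.size
            return same / pairs

        rng = np.random.default_rng(8)
        grid = np.ones((30, 30), dtype=int)
        grid[:10, :10] = 2  # one coherent patch of class 2
        r = make_raster(grid, scheme2)
        P = TransitionMatrix([[0.8, 0.2], [0.05, 0.95]], scheme2)
        out = predict(r, P, PredictionConfig(iterations=6))

        shuffled = out.grid.copy().ravel()
        rng.shuffle(shuffled)
        assert same_class_neighbour_fraction(out.grid) >= same_class_neighbour_fraction(
            shuffled.reshape(out.grid.shape)
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PredictionConfig(filter_size=4)
        with pytest.raises(ValueError):
            PredictionConfig(iterations=0)
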