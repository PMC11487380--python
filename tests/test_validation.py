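import math

import numpy as np
import pytest

from carbonscape import (
    AgreementComponents,
    ClassScheme,
    CrossTab,
    agreement_components,
    confusion_matrix,
    kappa_set,
)

# published component columns (4 dp) used as known inputs
COMPONENTS_2012 = dict(chance=0.1250, quantity=0.2976, stratum=0.0, gridcell=0.5575,
                       dis_gridcell=0.0140, dis_stratum=0.0, dis_quantity=0.0059)
COMPONENTS_2018 = dict(chance=0.1250, quantity=0.2973, stratum=0.0, gridcell=0.5669,
                       dis_gridcell=0.0084, dis_stratum=0.0, dis_quantity=0.0023)


def brute_force_stats(counts, J_chance):
    """Independent oracle: M, N(m), P(m) straight from the confusion matrix."""
    p = np.asarray(counts, dtype=float) / np.sum(counts)
    M = sum(p[i, i] for i in range(p.shape[0]))
    sim = p.sum(axis=1)
    ref = p.sum(axis=0)
    N_m = sum(sim[j] * ref[j] for j in range(p.shape[0]))
    P_m = sum(min(sim[j], ref[j]) for j in range(p.shape[0]))
    return M, 1.0 / J_chance, N_m, P_m


class TestConfusionMatrix:
    def test_identical_maps_put_all_mass_on_diagonal(self, random_pair):
        sim, _ = random_pair(seed=0)
        cm = confusion_matrix(sim, sim)
        assert cm.counts.sum() == np.trace(cm.counts) == sim.n_valid

    def test_single_cell_difference(self, make_raster, scheme2):
        sim = make_raster([[1, 1], [2, 2]], scheme2)
        ref = make_raster([[1, 2], [2, 2]], scheme2)
        cm = confusion_matrix(sim, ref)
        assert cm.counts[0, 1] == 1
        assert np.trace(cm.counts) == 3


class TestAgreementComponents:
    def test_perfect_agreement_equal_marginals(self, scheme7):
        """c_j = r_j = 1/8 over 8 populated entries isn't realisable with 7
        classes, so use a direct 8-class perfect matrix: chance = 1/8,
        quantity = 0, gridcell = 7/8, all disagreements 0."""
        scheme8 = ClassScheme(tuple(range(1, 9)), tuple("abcdefgh"))
        cm = CrossTab(np.eye(8, dtype=int) * 10, scheme8)
        ac = agreement_components(cm, J_chance=8)
        assert ac.chance == pytest.approx(0.125)
        assert ac.quantity == pytest.approx(0.0)
        assert ac.gridcell == pytest.approx(0.875)
        assert ac.dis_gridcell == pytest.approx(0.0)
        assert ac.dis_quantity == pytest.approx(0.0)

    def test_maximally_misallocated_two_classes(self, scheme2):
        cm = CrossTab([[0, 5], [5, 0]], scheme2)
        ac = agreement_components(cm, J_chance=2)
        assert ac.M == pytest.approx(0.0)
        assert ac.dis_gridcell == pytest.approx(1.0)
        assert ac.dis_quantity == pytest.approx(0.0)

    def test_published_2012_column_sums_to_one(self):
        assert sum(COMPONENTS_2012.values()) == pytest.approx(1.0, abs=1e-9)

    def test_components_sum_to_one_and_nonnegative_on_random_rasters(self, random_pair):
        for seed in range(8):
            sim, ref = random_pair(seed=seed, shape=(15, 18), nodata_frac=0.1)
            ac = agreement_components(confusion_matrix(sim, ref))
            parts = [ac.chance, ac.quantity, ac.stratum, ac.gridcell,
                     ac.dis_gridcell, ac.dis_stratum, ac.dis_quantity]
            assert sum(parts) == pytest.approx(1.0, abs=1e-9)
            assert all(p >= -1e-12 for p in parts)

    def test_empty_matrix_rejected(self, scheme2):
        with pytest.raises(ValueError, match="empty"):
            agreement_components(CrossTab(np.zeros((2, 2), int), scheme2))


class TestKappaSet:
    def test_identical_maps_give_unit_kappas(self, random_pair):
        sim, _ = random_pair(seed=2)
        ks = kappa_set(agreement_components(confusion_matrix(sim, sim)))
        assert ks.Kno == pytest.approx(1.0)
        assert ks.Kstd == pytest.approx(1.0)
        assert ks.Kloc == pytest.approx(1.0)
        assert ks.Klocstrata == ks.Kloc

    @pytest.mark.parametrize(
        "components,expected",
        [
            (COMPONENTS_2012, dict(Kstd=0.9656, Kno=0.9773, Kloc=0.9755)),
            (COMPONENTS_2018, dict(Kstd=0.9814, Kno=0.9877, Kloc=0.9854)),
        ],
        ids=["2012", "2018"],
    )
    def test_published_components_reproduce_published_kappas(self, components, expected):
        ks = kappa_set(AgreementComponents(**components, J_chance=8))
        for name, value in expected.items():
            assert getattr(ks, name) == pytest.approx(value, abs=1e-3)

    def test_oracle_equivalence_on_correlated_rasters(self, correlated_pair):
        """kappa_set . agreement_components must match brute-force M/N(m)/P(m).

        The component decomposition clamps at zero, so it is invertible (and
        this equivalence exact) whenever observed agreement beats the chance
        and quantity baselines — the regime of any usable validation run.
        """
        for seed in range(10):
            sim, ref = correlated_pair(seed=100 + seed, shape=(12, 12))
            cm = confusion_matrix(sim, ref)
            ks = kappa_set(agreement_components(cm, J_chance=8))
            M, N_n, N_m, P_m = brute_force_stats(cm.counts, J_chance=8)
            assert ks.Kno == pytest.approx((M - N_n) / (1 - N_n), abs=1e-12)
            assert ks.Kstd == pytest.approx((M - N_m) / (1 - N_m), abs=1e-12)
            assert ks.Kloc == pytest.approx((M - N_m) / (P_m - N_m), abs=1e-12)

    def test_kloc_at_least_kstd_when_quantity_error_present(self, random_pair):
        for seed in range(10):
            sim, ref = random_pair(seed=200 + seed)
            ac = agreement_components(confusion_matrix(sim, ref))
            ks = kappa_set(ac)
            if ac.P_m < 1 and not math.isnan(ks.Kloc):
                assert ks.Kloc >= ks.Kstd - 1e-12

    def test_degenerate_denominator_reports_nan(self, scheme2):
        # P(m) == N(m) == M == 1: perfect single-class map with J_chance=1
        cm = CrossTab([[4, 0], [0, 0]], scheme2)
        ks = kappa_set(agreement_components(cm, J_chance=1))
        assert math.isnan(ks.Kloc)
        assert math.isnan(ks.Kstd)
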