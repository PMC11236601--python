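import numpy as np
import pandas as pd
import pytest
from scipy import stats

import heteropool as hp
from heteropool import validation
from heteropool.gblup import MarkerEffects
from heteropool.synthetic import GeneticMap
from heteropool.usefulness import (compare_cross_sets, gebv_score,
                                   selection_intensity, simulate_dh,
                                   usefulness_criterion)


def _map_two(d_cM):
    return GeneticMap(pd.DataFrame({"marker": ["A", "B"], "chrom": [1, 1],
                                    "cm": [0.0, d_cM]}))


def _fx(markers, effects):
    return MarkerEffects(table=pd.DataFrame({"marker": markers,
                                             "effect": effects}))


class TestSimulateDH:
    def test_selfing_identical_parents_gives_clonal_progeny(self):
        gmap = _map_two(20.0)
        p = np.array([2, 0])
        pop = simulate_dh(p, p, gmap, np.array(["A", "B"], dtype=object),
                          n=50, seed=0)
        assert (pop.dosage == p[None, :]).all()
        vals = gebv_score(pop, _fx(["A", "B"], [0.3, -0.2]), site_mean=5.0)
        assert np.std(vals) < 1e-12

    def test_heterozygous_parent_rejected(self):
        gmap = _map_two(10.0)
        with pytest.raises(ValueError, match="homozygous"):
            simulate_dh(np.array([1, 0]), np.array([0, 0]), gmap,
                        np.array(["A", "B"], dtype=object), n=5, seed=0)

    def test_recombination_matches_haldane(self):
        out = validation.dh_recombination_calibration(seed=2)
        assert abs(out["recombination_fraction"]
                   - out["haldane_expected"]) < 0.01
        assert out["all_homozygous"]

    def test_segregation_frequency_near_half(self):
        gmap = _map_two(50.0)
        pop = simulate_dh(np.array([0, 0]), np.array([2, 2]), gmap,
                          np.array(["A", "B"], dtype=object), n=250, seed=3)
        freq = pop.dosage.mean(axis=0) / 2.0
        se = np.sqrt(0.25 / 250)
        assert np.abs(freq - 0.5).max() < 3 * se

    def test_recombination_monotone_in_distance_capped(self):
        prev = 0.0
        for d in [1.0, 5.0, 20.0, 80.0, 300.0]:
            gmap = _map_two(d)
            pop = simulate_dh(np.array([0, 0]), np.array([2, 2]), gmap,
                              np.array(["A", "B"], dtype=object), n=4000,
                              seed=int(d))
            r = float(np.mean(pop.dosage[:, 0] != pop.dosage[:, 1]))
            assert r >= prev - 0.03
            assert r <= 0.55
            prev = r

    def test_progeny_counts_binomial_consistent(self):
        # aggregate chi-square GOF across segregating loci at alpha=0.001
        gmap = GeneticMap(pd.DataFrame({
            "marker": [f"M{j}" for j in range(20)],
            "chrom": np.repeat([1, 2], 10),
            "cm": np.tile(np.linspace(0, 180, 10), 2)}))
        p1 = np.zeros(20)
        p2 = np.full(20, 2)
        pop = simulate_dh(p1, p2, gmap,
                          np.array([f"M{j}" for j in range(20)], dtype=object),
                          n=300, seed=4)
        counts = (pop.dosage == 2).sum(axis=0)
        chi2 = np.sum((counts - 150.0) ** 2 / (300 * 0.25))
        assert chi2 < stats.chi2.ppf(0.999, df=20)

    def test_unmapped_markers_excluded_with_warning(self):
        gmap = _map_two(10.0)
        with pytest.warns(UserWarning, match="without map positions"):
            pop = simulate_dh(np.array([0, 0, 2]), np.array([2, 2, 2]), gmap,
                              np.array(["A", "B", "ZZZ"], dtype=object),
                              n=10, seed=0)
        assert list(pop.marker_ids) == ["A", "B"]

    def test_reproducible_under_seed(self):
        gmap = _map_two(30.0)
        a = simulate_dh(np.array([0, 2]), np.array([2, 0]), gmap,
                        np.array(["A", "B"], dtype=object), n=40, seed=9)
        b = simulate_dh(np.array([0, 2]), np.array([2, 0]), gmap,
                        np.array(["A", "B"], dtype=object), n=40, seed=9)
        np.testing.assert_array_equal(a.dosage, b.dosage)


class TestGEBVScore:
    def test_zero_effects_give_site_mean(self):
        gmap = _map_two(10.0)
        pop = simulate_dh(np.array([0, 2]), np.array([2, 0]), gmap,
                          np.array(["A", "B"], dtype=object), n=20, seed=1)
        vals = gebv_score(pop, _fx(["A", "B"], [0.0, 0.0]), site_mean=6.5)
        np.testing.assert_allclose(vals, 6.5)

    def test_single_marker_two_point_support(self):
        gmap = GeneticMap(pd.DataFrame({"marker": ["A"], "chrom": [1],
                                        "cm": [0.0]}))
        pop = simulate_dh(np.array([0]), np.array([2]), gmap,
                          np.array(["A"], dtype=object), n=100, seed=2)
        vals = gebv_score(pop, _fx(["A"], [0.1]), site_mean=5.0)
        assert set(np.round(vals, 10)) <= {5.0, 5.2}

    def test_hand_dot_product(self):
        pop = hp.DHPopulation(dosage=np.array([[0, 2, 2], [2, 0, 2]],
                                              dtype=np.int8),
                              marker_ids=np.array(["A", "B", "C"],
                                                  dtype=object),
                              parent1="P1", parent2="P2", seed=0)
        vals = gebv_score(pop, _fx(["A", "B", "C"], [0.1, -0.2, 0.05]),
                          site_mean=1.0)
        np.testing.assert_allclose(vals, [1.0 - 0.4 + 0.1,
                                          1.0 + 0.2 + 0.1])

    def test_missing_effect_rejected(self):
        pop = hp.DHPopulation(dosage=np.zeros((2, 2), dtype=np.int8),
                              marker_ids=np.array(["A", "B"], dtype=object),
                              parent1="P1", parent2="P2", seed=0)
        with pytest.raises(ValueError, match="missing"):
            gebv_score(pop, _fx(["A"], [0.1]))


class TestSelectionIntensityAndUC:
    def test_half_selected_closed_form(self):
        assert selection_intensity(0.5) == pytest.approx(np.sqrt(2 / np.pi))

    def test_nearly_all_selected_tends_to_zero(self):
        assert selection_intensity(0.999) < 0.01

    def test_monte_carlo_truncated_normal_cross_check(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(2_000_000)
        p = 0.10
        cut = np.quantile(z, 1 - p)
        mc = z[z >= cut].mean()
        assert selection_intensity(p) == pytest.approx(mc, abs=5e-3)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fraction_rejected(self, p):
        with pytest.raises(ValueError):
            selection_intensity(p)

    def test_uc_identity_and_degenerate_cases(self, rng):
        vals = rng.normal(6.0, 0.5, 400)
        r = usefulness_criterion(vals, p=0.1, h=0.8)
        assert r.uc == pytest.approx(r.mu + r.intensity * 0.8 * r.sigma)
        assert r.sigma == pytest.approx(np.std(vals, ddof=1))
        flat = usefulness_criterion(np.full(10, 4.2), p=0.1)
        assert flat.uc == pytest.approx(4.2)
        no_acc = usefulness_criterion(vals, p=0.1, h=0.0)
        assert no_acc.uc == pytest.approx(no_acc.mu)

    def test_uc_strictly_increasing_in_sigma(self):
        base = np.array([5.0, 7.0])
        wide = np.array([4.0, 8.0])
        a = usefulness_criterion(base, p=0.2)
        b = usefulness_criterion(wide, p=0.2)
        assert b.uc > a.uc


class TestCompareCrossSets:
    def test_zero_effects_flatten_all_categories(self):
        panel, gmap, _ = validation.complementary_panel(seed=0)
        zero = _fx(list(panel.genotypes.marker_ids),
                   np.zeros(panel.genotypes.n_markers))
        uc = compare_cross_sets(panel, anchor_group=1,
                                effects_by_site={"S1": zero}, gmap=gmap,
                                site_means={"S1": 6.0}, n=20, seed=0,
                                max_crosses_per_pair=5)
        np.testing.assert_allclose(uc["uc"], 6.0, atol=1e-12)

    def test_category_bookkeeping(self):
        panel, gmap, fx = validation.complementary_panel(seed=1)
        uc = compare_cross_sets(panel, anchor_group=1,
                                effects_by_site={"S1": fx, "S2": fx},
                                gmap=gmap, n=10, seed=1,
                                max_crosses_per_pair=4)
        counts = uc.groupby("category")[["parent1"]].count()
        # 4 crosses per category per site, 2 sites
        assert (counts["parent1"] == 8).all()
        assert set(uc["category"]) == {"intra", "inter:G2", "inter:G3"}

    def test_missing_anchor_rejected(self):
        panel, gmap, fx = validation.complementary_panel(seed=2)
        with pytest.raises(ValueError, match="anchor"):
            compare_cross_sets(panel, anchor_group=9,
                               effects_by_site={"S1": fx}, gmap=gmap, n=5,
                               seed=0)

    def test_complementary_pools_raise_inter_population_uc(self):
        out = validation.uc_contrast(n_seeds=5, seed0=50, n_dh=60)
        assert out["success_rate"] >= 0.8
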