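import itertools

import numpy as np
import pytest

import heteropool as hp
from heteropool.genomics import (admixture_fit, filter_markers, pcoa,
                                 prune_complete_ld, rogers_distance,
                                 select_K_cv)
from heteropool.synthetic import GenotypeMatrix


def _gm(dosage, missing=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    return GenotypeMatrix(dosage=dosage,
                          individual_ids=[f"I{i}" for i in range(n)],
                          marker_ids=[f"M{j}" for j in range(m)],
                          missing=missing)


class TestFilterMarkers:
    def test_heterozygosity_and_missing_thresholds(self):
        # 10 individuals; markers crossing het fractions {0, .2, .6} with
        # missing fractions {0, .05→0/10 impossible, use 0, .1, .2}
        n = 10
        cols = []
        expected_keep = []
        for het_n, miss_n in itertools.product([0, 2, 6], [0, 1, 2]):
            col = np.zeros(n, dtype=np.int8)
            col[:het_n] = 1
            miss = np.zeros(n, dtype=bool)
            miss[n - miss_n:] = miss_n > 0
            # het fraction among observed calls
            het_frac = het_n / (n - miss_n)
            cols.append((col, miss))
            expected_keep.append(het_frac <= 0.5 and miss_n / n <= 0.1)
        dosage = np.column_stack([c for c, _ in cols])
        missing = np.column_stack([m for _, m in cols])
        g = filter_markers(_gm(dosage, missing))
        kept = [f"M{j}" for j, k in enumerate(expected_keep) if k]
        assert list(g.marker_ids) == kept

    def test_majority_heterozygous_marker_excluded(self):
        col_bad = np.array([1] * 6 + [0] * 4)     # 60% het
        col_ok = np.array([0] * 5 + [2] * 5)      # 0% het
        g = filter_markers(_gm(np.column_stack([col_bad, col_ok])))
        assert list(g.marker_ids) == ["M1"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_markers(_gm(np.zeros((0, 3))))


class TestPruneCompleteLD:
    def test_duplicate_and_complement_each_leave_one(self):
        base = np.array([0, 2, 2, 0, 2, 0, 0, 2], dtype=np.int8)
        other = np.array([0, 0, 2, 2, 2, 0, 2, 0], dtype=np.int8)
        g = prune_complete_ld(_gm(np.column_stack([base, base, 2 - base,
                                                   other])))
        assert list(g.marker_ids) == ["M0", "M3"]

    def test_monomorphic_dropped_first(self):
        mono = np.full(6, 2, dtype=np.int8)
        poly = np.array([0, 2, 0, 2, 0, 2], dtype=np.int8)
        g = prune_complete_ld(_gm(np.column_stack([mono, poly])))
        assert list(g.marker_ids) == ["M1"]

    def test_against_bruteforce_all_pairs(self, rng):
        base = (2 * rng.integers(0, 2, size=(30, 50))).astype(np.int8)
        dup_src = rng.choice(50, size=5, replace=False)
        planted = np.column_stack([base] + [base[:, j][:, None]
                                            for j in dup_src])
        g_in = _gm(planted)
        g = prune_complete_ld(g_in)
        # brute-force oracle: greedy first-kept scan over all pairs
        x = planted.astype(float)
        var = x.var(axis=0)
        keep = [j for j in range(x.shape[1]) if var[j] > 0]
        survivors = []
        for j in keep:
            dup = any(abs(np.corrcoef(x[:, j], x[:, s])[0, 1]) >= 1 - 1e-12
                      for s in survivors)
            if not dup:
                survivors.append(j)
        assert list(g.marker_ids) == [g_in.marker_ids[j] for j in survivors]

    def test_qc_pipeline_idempotent(self, rng):
        dosage = (2 * rng.integers(0, 2, size=(20, 40))).astype(np.int8)
        dosage[:, 5] = dosage[:, 3]
        once = prune_complete_ld(filter_markers(_gm(dosage)))
        twice = prune_complete_ld(filter_markers(once))
        assert list(once.marker_ids) == list(twice.marker_ids)
        assert np.array_equal(once.dosage, twice.dosage)


class TestRogersDistance:
    def test_identical_opposite_and_half(self):
        a = np.zeros(10, dtype=np.int8)
        b = np.full(10, 2, dtype=np.int8)
        half = np.array([2] * 5 + [0] * 5, dtype=np.int8)
        d = rogers_distance(_gm(np.vstack([a, a, b, half])))
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d.values[0, 2] == pytest.approx(1.0, abs=1e-12)
        assert d.values[0, 3] == pytest.approx(0.5, abs=1e-12)

    def test_heterozygote_midpoint(self):
        # dosage 1 vs 0: per-locus distance |1-0|/2 = 0.5
        a = np.zeros(4, dtype=np.int8)
        h = np.ones(4, dtype=np.int8)
        d = rogers_distance(_gm(np.vstack([a, h])))
        assert d.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_triangle_inequality_exhaustive(self):
        p = hp.simulate_founders(K=3, n_per_group=4, n_markers=60, fst=0.25,
                                 seed=4)
        d = p.genotypes
        D = rogers_distance(d).values
        n = D.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_no_shared_loci_error_names_pair(self):
        miss = np.array([[False, True], [True, False]])
        g = _gm(np.zeros((2, 2)), missing=miss)
        with pytest.raises(ValueError, match="I0"):
            rogers_distance(g)


class TestPCoA:
    def test_line_configuration_reconstructed(self):
        pos = np.array([0.0, 0.1, 0.35, 0.7, 1.0])
        D = np.abs(pos[:, None] - pos[None, :])
        from heteropool.genomics import DistanceMatrix
        res = pcoa(DistanceMatrix(values=D,
                                  individual_ids=[f"I{i}" for i in range(5)]),
                   n_axes=2)
        ax1 = res.coordinates[:, 0]
        recon = np.abs(ax1[:, None] - ax1[None, :])
        np.testing.assert_allclose(recon, D, atol=1e-8)

    def test_equilateral_triangle_has_two_equal_eigenvalues(self):
        from heteropool.genomics import DistanceMatrix
        D = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(values=D, individual_ids=list("abc")))
        w = res.eigenvalues
        assert w[0] == pytest.approx(w[1], rel=1e-10)
        assert w[2] == pytest.approx(0.0, abs=1e-10)

    def test_euclidean_distances_reproduced(self, rng):
        pts = rng.normal(size=(12, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        D = D / D.max()
        from heteropool.genomics import DistanceMatrix
        res = pcoa(DistanceMatrix(values=D,
                                  individual_ids=[f"I{i}" for i in range(12)]),
                   n_axes=3)
        C = res.coordinates
        recon = np.linalg.norm(C[:, None] - C[None, :], axis=-1)
        np.testing.assert_allclose(recon, D, atol=1e-8)


class TestAdmixture:
    def test_k1_closed_form(self):
        p = hp.simulate_founders(K=1, n_per_group=10, n_markers=40, fst=0.3,
                                 seed=5)
        fit = admixture_fit(p.genotypes, K=1)
        np.testing.assert_allclose(fit.Q, 1.0)
        np.testing.assert_allclose(fit.P[0], p.genotypes.allele_freq(),
                                   atol=1e-12)

    def test_fully_diverged_populations_resolved(self):
        n, m = 12, 80
        dosage = np.zeros((n, m), dtype=np.int8)
        dosage[n // 2:, :] = 2
        fit = admixture_fit(_gm(dosage), K=2, seed=0)
        own = fit.Q.max(axis=1)
        assert (own >= 0.99).all()
        # memberships agree within each true population
        top = fit.Q.argmax(axis=1)
        assert len(set(top[:n // 2])) == 1 and len(set(top[n // 2:])) == 1
        assert top[0] != top[-1]

    def test_rows_on_simplex_and_monotone_loglik(self):
        p = hp.simulate_founders(K=2, n_per_group=8, n_markers=60, fst=0.2,
                                 seed=6)
        fit = admixture_fit(p.genotypes, K=3, seed=1)
        np.testing.assert_allclose(fit.Q.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(np.diff(fit.loglik_path) >= -1e-7)

    def test_invalid_k(self):
        p = hp.simulate_founders(K=1, n_per_group=4, n_markers=10, fst=0.2,
                                 seed=0)
        with pytest.raises(ValueError):
            admixture_fit(p.genotypes, K=0)


class TestSelectKCV:
    def test_trivial_range_and_curve_bookkeeping(self):
        p = hp.simulate_founders(K=2, n_per_group=10, n_markers=80, fst=0.3,
                                 seed=7)
        K, curve = select_K_cv(p.genotypes, k_min=2, k_max=2, folds=3, seed=0)
        assert K == 2
        K, curve = select_K_cv(p.genotypes, k_min=2, k_max=4, folds=3, seed=0,
                               max_iter=200)
        assert sorted(curve) == [2, 3, 4]
        assert all(len(v) == 3 for v in curve.values())

    def test_bad_arguments(self):
        p = hp.simulate_founders(K=1, n_per_group=4, n_markers=10, fst=0.2,
                                 seed=0)
        with pytest.raises(ValueError):
            select_K_cv(p.genotypes, k_min=5, k_max=3)
        with pytest.raises(ValueError):
            select_K_cv(p.genotypes, k_min=2, k_max=3, folds=1)
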