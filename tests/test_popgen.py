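"""Diversity estimators, F-statistics, PCA and structure inference."""

from fractions import Fraction

import numpy as np
import pytest

from gbscompare.genotypes import MISSING
from gbscompare.popgen import (
    FoldedSFS,
    expected_neutral_folded_sfs,
    f_statistics,
    folded_sfs,
    heterozygosity,
    infer_structure,
    match_assignments,
    pca,
    tajima_constants,
    tajimas_d,
    theta_pi,
    theta_watterson,
)
from conftest import make_gm


class TestFoldedSFS:
    def test_single_het_site(self):
        sfs = folded_sfs(make_gm([[0], [1]]))
        assert sfs.n_chrom == 4
        np.testing.assert_array_equal(sfs.bins, [1, 0])

    def test_monomorphic_contributes_nothing(self):
        sfs = folded_sfs(make_gm([[0, 2], [0, 2]]))
        assert sfs.S == 0

    def test_direct_tally(self):
        # 3 diploids (6 chrom), minor counts 1, 1, 2
        G = [[1, 0, 1], [0, 1, 1], [0, 0, 0]]
        sfs = folded_sfs(make_gm(G))
        np.testing.assert_array_equal(sfs.bins, [2, 1, 0])

    def test_all_missing_site_rejected(self):
        with pytest.raises(ValueError):
            folded_sfs(make_gm([[MISSING], [MISSING]]))

    def test_projection_conserves_when_complete(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, size=(6, 50))
        a = folded_sfs(make_gm(G), mode="project")
        b = folded_sfs(make_gm(G), mode="raw")
        np.testing.assert_allclose(a.bins, b.bins)


class TestExpectedSFS:
    def test_four_chromosomes_eleven_sites(self):
        # fold of E[xi_i] = theta/i for i=1..3: proportions (4/3):(1/2)
        np.testing.assert_allclose(expected_neutral_folded_sfs(4, 11), [8.0, 3.0])

    def test_two_chromosomes_single_bin(self):
        np.testing.assert_allclose(expected_neutral_folded_sfs(2, 7), [7.0])

    def test_zero_sites(self):
        np.testing.assert_array_equal(expected_neutral_folded_sfs(10, 0), np.zeros(5))

    def test_sums_to_S(self):
        for n in (4, 9, 50):
            assert expected_neutral_folded_sfs(n, 123).sum() == pytest.approx(123.0)


def _exact_constants(n):
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    return {
        "a1": a1, "a2": a2, "b1": b1, "b2": b2,
        "c1": c1, "c2": c2, "e1": c1 / a1, "e2": c2 / (a1**2 + a2),
    }


class TestThetaAndD:
    def test_watterson_worked_example(self):
        assert theta_watterson(3, 4) == pytest.approx(18 / 11)

    def test_pi_single_het_individual(self):
        assert theta_pi(make_gm([[1]])) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 10, 182])
    def test_constants_match_exact_fractions(self, n):
        exact = _exact_constants(n)
        got = tajima_constants(n)
        for k, v in exact.items():
            assert got[k] == pytest.approx(float(v), rel=1e-12)

    def test_d_nan_when_no_segregating_sites(self):
        d = tajimas_d(make_gm([[0, 0], [0, 0]]))
        assert d.S == 0 and np.isnan(d.tajimas_d)

    def test_d_sign_tracks_pi_minus_thetaw(self):
        # excess of intermediate-frequency variants -> positive D
        G_mid = [[1] * 10, [1] * 10, [1] * 10, [1] * 10]
        d_mid = tajimas_d(make_gm(G_mid))
        assert d_mid.theta_pi > d_mid.theta_w and d_mid.tajimas_d > 0
        # all singletons -> negative D
        G_rare = np.zeros((4, 10), dtype=int)
        G_rare[0, :] = 1
        d_rare = tajimas_d(make_gm(G_rare.tolist()))
        assert d_rare.tajimas_d < 0


class TestHeterozygosity:
    def test_worked_example(self):
        h = heterozygosity(make_gm([[0], [1], [1], [2]]))
        assert h.h_obs[0] == pytest.approx(0.5)
        assert h.h_exp[0] == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        h = heterozygosity(make_gm([[0], [0]]))
        assert h.h_obs[0] == 0.0 and h.h_exp[0] == 0.0

    def test_all_heterozygous(self):
        h = heterozygosity(make_gm([[1], [1], [1]]))
        assert h.h_obs[0] == 1.0


class TestFStatistics:
    def test_fixed_demes_give_fst_one(self):
        G = [[0, 0], [0, 0], [2, 2], [2, 2]]
        fs = f_statistics(make_gm(G), ["a", "a", "b", "b"])
        assert fs.fst_multilocus == pytest.approx(1.0)
        assert np.allclose(fs.loci["fst"], 1.0)

    def test_all_het_negative_fis(self):
        G = [[1], [1], [1], [1]]
        fs = f_statistics(make_gm(G), ["a", "a", "b", "b"])
        assert (fs.loci["fis"] < 0).all()

    def test_single_deme_rejected(self):
        with pytest.raises(ValueError):
            f_statistics(make_gm([[0], [1]]), ["a", "a"])

    def test_monomorphic_excluded_with_count(self):
        G = [[0, 1], [0, 1], [0, 0], [0, 2]]
        fs = f_statistics(make_gm(G), ["a", "a", "b", "b"])
        assert fs.n_monomorphic_excluded == 1
        assert len(fs.loci) == 1

    def test_hwe_random_mating_fis_near_zero(self):
        # genotypes drawn at HWE: multi-locus F_IS ~ 0
        rng = np.random.default_rng(42)
        p = rng.uniform(0.2, 0.8, size=2000)
        G = (rng.random((20, 2000)) < p).astype(int) + (rng.random((20, 2000)) < p).astype(int)
        fs = f_statistics(make_gm(G.tolist()), ["a"] * 10 + ["b"] * 10)
        assert abs(fs.fis_multilocus) < 0.03
        assert abs(fs.fst_multilocus) < 0.03


class TestPca:
    def _two_cluster_gm(self, n=10, m=80, seed=0):
        rng = np.random.default_rng(seed)
        G = np.zeros((2 * n, m), dtype=int)
        G[n:, : m // 2] = 2
        G += (rng.random(G.shape) < 0.05).astype(int)
        np.clip(G, 0, 2, out=G)
        return make_gm(G.tolist())

    def test_two_clusters_separate_on_pc1(self):
        from sklearn.metrics import silhouette_score

        gm = self._two_cluster_gm()
        res = pca(gm)
        labels = [0] * 10 + [1] * 10
        assert silhouette_score(res.coords[:, :1], labels) > 0.8

    def test_duplicated_samples_identical_coords(self):
        gm = self._two_cluster_gm()
        G2 = np.vstack([gm.G, gm.G[:1]])
        gm2 = make_gm(G2.tolist())
        res = pca(gm2)
        np.testing.assert_allclose(res.coords[0], res.coords[-1], atol=1e-9)

    def test_monomorphic_columns_dropped(self):
        gm = self._two_cluster_gm()
        G_plus = np.hstack([gm.G, np.ones((gm.n_samples, 3), dtype=int) * 2])
        res_a = pca(gm)
        res_b = pca(make_gm(G_plus.tolist()))
        np.testing.assert_allclose(res_a.coords, res_b.coords, atol=1e-9)

    def test_site_permutation_invariant(self):
        gm = self._two_cluster_gm()
        rng = np.random.default_rng(3)
        perm = rng.permutation(gm.n_sites)
        res_a = pca(gm)
        res_b = pca(gm.take_sites(perm))
        np.testing.assert_allclose(res_a.coords, res_b.coords, atol=1e-8)

    def test_eigenvalues_non_increasing(self):
        res = pca(self._two_cluster_gm())
        assert (np.diff(res.eigenvalues) <= 1e-9).all()

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            pca(make_gm([[2, 2], [2, 2], [2, 2]]))


class TestStructure:
    def _three_deme_gm(self, seed=0):
        rng = np.random.default_rng(seed)
        freqs = rng.uniform(0.05, 0.95, size=(3, 300))
        # strong divergence: each deme fixes a private subset
        for k in range(3):
            freqs[k, k * 100 : (k + 1) * 100] = 0.95
            freqs[k, ((k + 1) % 3) * 100 : ((k + 1) % 3 + 1) * 100] = 0.05
        G = np.zeros((30, 300), dtype=int)
        for i in range(30):
            p = freqs[i // 10]
            G[i] = (rng.random(300) < p).astype(int) + (rng.random(300) < p).astype(int)
        return make_gm(G.tolist()), ["d0"] * 10 + ["d1"] * 10 + ["d2"] * 10

    def test_k1_trivial(self):
        gm, _ = self._three_deme_gm()
        res = infer_structure(gm, 1)
        np.testing.assert_allclose(res.Q, 1.0)

    def test_rows_sum_to_one(self):
        gm, _ = self._three_deme_gm()
        res = infer_structure(gm, 3, seed=1)
        np.testing.assert_allclose(res.Q.sum(axis=1), 1.0, atol=1e-9)

    def test_recovers_three_demes(self):
        gm, labels = self._three_deme_gm()
        res = infer_structure(gm, 3, seed=1)
        assert match_assignments(res.assignment, labels) >= 0.95

    def test_identical_samples_identical_rows(self):
        gm, _ = self._three_deme_gm()
        G2 = np.vstack([gm.G, gm.G[:1]])
        res = infer_structure(make_gm(G2.tolist()), 3, seed=1)
        np.testing.assert_allclose(res.Q[0], res.Q[-1], atol=1e-6)

    def test_k_exceeding_samples_rejected(self):
        with pytest.raises(ValueError):
            infer_structure(make_gm([[0], [1]]), 3)
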