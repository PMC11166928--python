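import numpy as np
import pytest

from landcnn.popgen import FstMatrix, heterozygosity, pairwise_fst, pca_match
from landcnn.simulate import GenotypeMatrix


def brute_force_hudson(g, deme_a, deme_b):
    """Per-SNP hand formula, written independently of the implementation."""
    rows_a = g.genotypes[g.deme_ids == deme_a].astype(float)
    rows_b = g.genotypes[g.deme_ids == deme_b].astype(float)
    n1, n2 = rows_a.shape[0], rows_b.shape[0]
    nums, dens = [], []
    for snp in range(g.n_snps):
        p1 = rows_a[:, snp].sum() / n1
        p2 = rows_b[:, snp].sum() / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        nums.append(num)
        dens.append(den)
    return sum(nums) / sum(dens)


def matrix_from(genos, demes):
    genos = np.asarray(genos, dtype=np.uint8)
    demes = np.asarray(demes)
    return GenotypeMatrix(
        genotypes=genos, deme_ids=demes,
        individual_ids=np.arange(len(demes)) // 2 + 1,
    )


class TestHudsonFst:
    def test_hand_calculated_toy_value(self):
        """p1=0.9, p2=0.1, n1=n2=10: N = 0.64 - 2*0.009 = 0.622? No:
        0.09/9 = 0.01 each side -> N = 0.62, D = 0.81 + 0.01 = 0.82,
        F_ST = 0.62/0.82."""
        genos = np.zeros((20, 1), dtype=np.uint8)
        genos[:9, 0] = 1       # deme 1: p1 = 0.9
        genos[10:11, 0] = 1    # deme 2: p2 = 0.1
        demes = np.array([1] * 10 + [2] * 10)
        g = matrix_from(genos, demes)
        f = pairwise_fst(g)
        assert f.values[0, 1] == pytest.approx(0.62 / 0.82, abs=1e-12)

    def test_identical_frequencies_near_zero(self):
        # the unbiased estimator is slightly negative for identical finite
        # samples (within-deme variance correction), approaching 0 with n
        rng = np.random.default_rng(0)
        block = rng.integers(0, 2, size=(100, 50)).astype(np.uint8)
        block[0] = 1  # guard against monomorphic columns
        block[1] = 0
        g = matrix_from(np.vstack([block, block]), [1] * 100 + [2] * 100)
        f = pairwise_fst(g).values[0, 1]
        assert f == pytest.approx(0.0, abs=0.03)
        assert f <= 0.0

    def test_fixed_differences_give_one(self):
        genos = np.vstack([np.ones((6, 20)), np.zeros((6, 20))]).astype(np.uint8)
        g = matrix_from(genos, [1] * 6 + [2] * 6)
        assert pairwise_fst(g).values[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_on_random_matrices(self):
        """Ratio-of-averages Hudson vs. an independent per-SNP hand formula,
        100 random toy matrices, exact to 1e-12."""
        rng = np.random.default_rng(77)
        for _ in range(100):
            n1, n2 = rng.integers(2, 8, size=2)
            n_snps = int(rng.integers(1, 12))
            while True:
                genos = rng.integers(0, 2, size=(n1 + n2, n_snps)).astype(np.uint8)
                s = genos.sum(axis=0)
                if np.all((s > 0) & (s < n1 + n2)):
                    break
            g = matrix_from(genos, [1] * n1 + [2] * n2)
            got = pairwise_fst(g).values[0, 1]
            want = brute_force_hudson(g, 1, 2)
            assert got == pytest.approx(want, abs=1e-12)

    def test_symmetric_and_deme_swap_invariant(self):
        rng = np.random.default_rng(5)
        genos = rng.integers(0, 2, size=(12, 30)).astype(np.uint8)
        genos[0], genos[1] = 1, 0
        g1 = matrix_from(genos, [1] * 6 + [2] * 6)
        g2 = matrix_from(genos, [2] * 6 + [1] * 6)
        f1, f2 = pairwise_fst(g1), pairwise_fst(g2)
        assert np.allclose(f1.values, f1.values.T)
        assert f1.values[0, 1] == pytest.approx(f2.values[0, 1])

    def test_undefined_for_single_sequence_deme(self):
        genos = np.array([[0, 1], [1, 0], [1, 1], [0, 1], [1, 0]], dtype=np.uint8)
        g = GenotypeMatrix(
            genotypes=genos,
            deme_ids=np.array([1, 1, 2, 2, 3]),
            individual_ids=np.array([1, 1, 2, 2, 3]),
        )
        f = pairwise_fst(g)
        assert np.isnan(f.values[0, 2]) and np.isnan(f.values[1, 2])
        assert not np.isnan(f.values[0, 1])


class TestHeterozygosity:
    def test_no_variation(self):
        g = matrix_from(np.zeros((4, 10)), [1, 1, 2, 2])
        he, ho = heterozygosity(g)
        assert he == 0.0 and ho == 0.0

    def test_all_heterozygous_single_snp(self):
        genos = np.array([[0], [1], [0], [1]], dtype=np.uint8)
        g = matrix_from(genos, [1, 1, 2, 2])
        he, ho = heterozygosity(g)
        assert ho == 1.0
        assert he == pytest.approx(2 * 0.5 * 0.5 * 4 / 3)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(1)
        genos = rng.integers(0, 2, size=(8, 20)).astype(np.uint8)
        g1 = matrix_from(genos, [1] * 4 + [2] * 4)
        g2 = matrix_from(genos[:, ::-1], [1] * 4 + [2] * 4)
        a, b = heterozygosity(g1), heterozygosity(g2)
        assert a[0] == pytest.approx(b[0]) and a[1] == pytest.approx(b[1])

    def test_odd_pairing_rejected(self):
        g = GenotypeMatrix(
            genotypes=np.array([[0, 1], [1, 0], [1, 1]], dtype=np.uint8),
            deme_ids=np.array([1, 1, 1]),
            individual_ids=np.array([1, 1, 2]),
        )
        with pytest.raises(ValueError, match="exactly 2"):
            heterozygosity(g)


class TestPcaMatch:
    @staticmethod
    def random_fsts(n, seed, n_demes=5):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            v = np.zeros((n_demes, n_demes))
            iu = np.triu_indices(n_demes, k=1)
            vals = rng.uniform(0.0, 0.8, size=iu[0].size)
            v[iu] = vals
            v += v.T
            out.append(FstMatrix(deme_ids=list(range(1, n_demes + 1)), values=v))
        return out

    def test_member_of_cloud_matches(self):
        sims = self.random_fsts(30, seed=0)
        rep = pca_match(sims, sims[7])
        assert rep.match and rep.within_ranges
        assert rep.distance_to_nearest == pytest.approx(0.0, abs=1e-9)

    def test_constructed_outlier_rejected(self):
        sims = self.random_fsts(30, seed=1)
        vecs = np.stack([f.lower_triangle() for f in sims])
        direction = vecs.std(axis=0)
        out_vec = vecs.mean(axis=0) + 10 * (vecs.max(axis=0) - vecs.mean(axis=0))
        n = sims[0].values.shape[0]
        outlier = np.zeros((n, n))
        il = np.tril_indices(n, k=-1)
        outlier[il] = out_vec
        outlier += outlier.T
        rep = pca_match(sims, FstMatrix(deme_ids=sims[0].deme_ids, values=outlier))
        assert not rep.match

    def test_degenerate_cloud_reports_not_crashes(self):
        base = self.random_fsts(1, seed=2)[0]
        sims = [FstMatrix(deme_ids=base.deme_ids, values=base.values.copy()) for _ in range(12)]
        rep = pca_match(sims, base)
        assert rep.degenerate and rep.match
        other = self.random_fsts(1, seed=3)[0]
        rep2 = pca_match(sims, other)
        assert rep2.degenerate and not rep2.match

    def test_leave_one_out_self_consistency(self):
        """Matrices drawn from one generating process almost always fall
        inside the cloud of the rest."""
        sims = self.random_fsts(50, seed=4)
        hits = sum(
            pca_match(sims[:i] + sims[i + 1:], sims[i]).match for i in range(50)
        )
        assert hits >= 45
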