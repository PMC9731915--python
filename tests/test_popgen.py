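"""Population-genetics statistics against independently coded oracles."""

import itertools

import numpy as np
import pytest

from ambropop import popgen
from ambropop.datatypes import MISSING, PairwiseMatrix
from conftest import make_genotypes, make_panel, random_micro_instance


# ------------------------------------------------------------------ oracles

def oracle_pi(dosages) -> float:
    """Mean over loci of pairwise allele differences / C(2n, 2), by explicit
    enumeration of every allele pair."""
    per_locus = []
    for row in dosages:
        alleles = []
        for d in row:
            if d != MISSING:
                alleles += [1] * d + [0] * (2 - d)
        if len(alleles) < 4:  # < 2 genotyped samples
            continue
        pairs = list(itertools.combinations(alleles, 2))
        per_locus.append(sum(a != b for a, b in pairs) / len(pairs))
    return float(np.mean(per_locus))


def oracle_het(dosages) -> tuple[float, float]:
    ho_l, he_l = [], []
    for row in dosages:
        called = [d for d in row if d != MISSING]
        if len(called) < 2:
            continue
        ho_l.append(sum(d == 1 for d in called) / len(called))
        p = sum(called) / (2 * len(called))
        he_l.append(2 * p * (1 - p))
    return float(np.mean(ho_l)), float(np.mean(he_l))


def oracle_wc_fst(d1, d2) -> float:
    """Scalar, per-locus transcription of the 1984 two-population
    variance-component estimator, ratio-of-sums across loci."""
    num = den = 0.0
    r = 2
    for row1, row2 in zip(d1, d2):
        g1 = [d for d in row1 if d != MISSING]
        g2 = [d for d in row2 if d != MISSING]
        n1, n2 = len(g1), len(g2)
        if n1 == 0 or n2 == 0:
            continue
        nbar = (n1 + n2) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        p1, p2 = sum(g1) / (2 * n1), sum(g2) / (2 * n2)
        h1 = sum(d == 1 for d in g1) / n1
        h2 = sum(d == 1 for d in g2) / n2
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


# ------------------------------------------------------- diversity & FST

class TestDiversity:
    def test_monomorphic_locus_pi_zero(self):
        m = make_genotypes(np.zeros((3, 4), dtype=int),
                           make_panel({"P": 4}).sample_ids)
        assert popgen.nucleotide_diversity(m, make_panel({"P": 4}), "P") == 0.0

    def test_pi_single_locus_half_half(self):
        # allele counts ref=2, alt=2 among 2 diploids -> 4/6
        panel = make_panel({"P": 2})
        m = make_genotypes(np.array([[1, 1]]), panel.sample_ids)
        assert popgen.nucleotide_diversity(m, panel, "P") == pytest.approx(4 / 6)

    def test_pi_mean_over_loci(self):
        panel = make_panel({"P": 2})
        m = make_genotypes(np.array([[0, 0], [1, 1]]), panel.sample_ids)
        assert popgen.nucleotide_diversity(m, panel, "P") == pytest.approx(1 / 3)

    def test_het_all_heterozygous(self):
        panel = make_panel({"P": 3})
        m = make_genotypes(np.ones((1, 3), dtype=int), panel.sample_ids)
        ho, he = popgen.heterozygosity(m, panel, "P")
        assert (ho, he) == (1.0, 0.5)

    def test_het_mixed_dosages(self):
        panel = make_panel({"P": 4})
        m = make_genotypes(np.array([[0, 1, 1, 2]]), panel.sample_ids)
        ho, he = popgen.heterozygosity(m, panel, "P")
        assert ho == pytest.approx(0.5)
        assert he == pytest.approx(0.5)

    def test_no_usable_locus_signalled(self):
        panel = make_panel({"P": 2})
        m = make_genotypes(np.full((1, 2), MISSING), panel.sample_ids)
        with pytest.raises(popgen.UndefinedStatisticError):
            popgen.nucleotide_diversity(m, panel, "P")


class TestFst:
    def test_fixed_difference_gives_one(self):
        panel = make_panel({"A": 5, "B": 5})
        d = np.hstack([np.zeros((10, 5), int), np.full((10, 5), 2)])
        m = make_genotypes(d, panel.sample_ids)
        assert popgen.wc_fst(m, panel, "A", "B") == pytest.approx(1.0)

    def test_identical_pops_near_zero(self):
        rng = np.random.default_rng(0)
        panel = make_panel({"A": 20, "B": 20})
        block = rng.binomial(2, 0.3, size=(200, 20))
        m = make_genotypes(np.hstack([block, block]), panel.sample_ids)
        fst = popgen.wc_fst(m, panel, "A", "B")
        assert fst <= 0 or abs(fst) < 0.05

    def test_matches_bruteforce_oracle_on_micro_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            m, panel = random_micro_instance(rng)
            pops = panel.populations
            sizes = {p: len(panel.samples_of(p)) for p in pops}
            start = {}
            s = 0
            for p in pops:
                start[p] = s
                s += sizes[p]
            for p1, p2 in itertools.combinations(pops, 2):
                d1 = m.dosage[:, start[p1]:start[p1] + sizes[p1]]
                d2 = m.dosage[:, start[p2]:start[p2] + sizes[p2]]
                expected = oracle_wc_fst(d1, d2)
                got = popgen.wc_fst(m, panel, p1, p2)
                assert got == pytest.approx(expected, abs=1e-12)

    def test_pi_het_match_oracles_on_micro_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m, panel = random_micro_instance(rng)
            s = 0
            for pop in panel.populations:
                n = len(panel.samples_of(pop))
                block = m.dosage[:, s:s + n]
                s += n
                assert popgen.nucleotide_diversity(m, panel, pop) == \
                    pytest.approx(oracle_pi(block), abs=1e-12)
                ho, he = popgen.heterozygosity(m, panel, pop)
                oho, ohe = oracle_het(block)
                assert ho == pytest.approx(oho, abs=1e-12)
                assert he == pytest.approx(ohe, abs=1e-12)


class TestReplicateFilter:
    def _matrix(self):
        panel = make_panel({"P1": 3, "P2": 2},
                           replicate_groups={"g": ["P1-1", "P1-2"]})
        # locus 0: concordant carriers; locus 1: discordant; locus 2: both zero
        d = np.array([[1, 1, 0, 2, 0],
                      [1, 0, 2, 0, 1],
                      [0, 0, 1, 1, 1]])
        return make_genotypes(d, panel.sample_ids), panel

    def test_discordant_locus_removed_only(self):
        m, panel = self._matrix()
        out, report = popgen.replicate_concordance_filter(m, panel)
        assert out.n_loci == 2
        assert list(report["pos"]) == [2]

    def test_no_replicates_identity(self):
        panel = make_panel({"P1": 3})
        m = make_genotypes(np.array([[0, 1, 2]]), panel.sample_ids)
        out, report = popgen.replicate_concordance_filter(m, panel)
        assert out.equals(m) and report.empty

    def test_dosage_one_vs_two_is_concordant(self):
        panel = make_panel({"P1": 2}, replicate_groups={"g": ["P1-1", "P1-2"]})
        m = make_genotypes(np.array([[1, 2]]), panel.sample_ids)
        out, _ = popgen.replicate_concordance_filter(m, panel)
        assert out.n_loci == 1


class TestGeography:
    def test_same_point_zero(self):
        assert popgen.haversine_km(40, -83, 40, -83) == 0.0

    def test_quarter_great_circle(self):
        assert popgen.haversine_km(0, 0, 0, 90) == \
            pytest.approx(6371 * np.pi / 2, rel=1e-9)

    def test_matrix_symmetric_zero_diagonal(self):
        panel = make_panel({"A": 2, "B": 2, "C": 2},
                           coords={"A": (40, -83), "B": (41, -84),
                                   "C": (42, -85)})
        km = popgen.geographic_distance(panel)
        assert np.allclose(km.matrix, km.matrix.T)
        assert np.allclose(np.diag(km.matrix), 0)


class TestMantel:
    def _mats(self, n=5, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.random((n, n))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        labels = tuple(f"L{i}" for i in range(n))
        return (PairwiseMatrix(labels, a), PairwiseMatrix(labels, b))

    def test_self_correlation_is_one(self):
        m1, _ = self._mats()
        r, _ = popgen.mantel_test(m1, m1, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_exact_enumeration_matches_independent_oracle(self):
        m1, m2 = self._mats(n=5, seed=3)
        r, p = popgen.mantel_test(m1, m2, exact=True)
        # oracle: enumerate all 120 relabelings with numpy directly
        iu = np.triu_indices(5, 1)
        x = m1.matrix[iu]
        count = total = 0
        for perm in itertools.permutations(range(5)):
            y = m2.matrix[np.ix_(perm, perm)][iu]
            count += np.corrcoef(x, y)[0, 1] >= r - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)
        assert total == 120

    def test_joint_relabeling_invariance(self):
        m1, m2 = self._mats(n=6, seed=4)
        r1, p1 = popgen.mantel_test(m1, m2, exact=True)
        perm = [3, 1, 4, 0, 5, 2]
        labels = tuple(m1.labels[i] for i in perm)
        m1p = PairwiseMatrix(labels, m1.matrix[np.ix_(perm, perm)])
        m2p = PairwiseMatrix(labels, m2.matrix[np.ix_(perm, perm)])
        r2, p2 = popgen.mantel_test(m1p, m2p, exact=True)
        assert r1 == pytest.approx(r2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_signalled(self):
        labels = tuple("abcd")
        flat = PairwiseMatrix(labels, 1 - np.eye(4))
        m1, _ = self._mats(n=4)
        m1 = PairwiseMatrix(labels, m1.matrix)
        with pytest.raises(popgen.UndefinedStatisticError):
            popgen.mantel_test(m1, flat, n_perm=9, seed=0)


class TestPcoaNj:
    def test_identical_samples_coincide(self):
        panel = make_panel({"P": 3})
        m = make_genotypes(np.tile([[1], [0], [2]], (1, 3)), panel.sample_ids)
        coords, _ = popgen.pcoa(m, panel)
        assert np.allclose(coords.to_numpy(), 0, atol=1e-9)

    def test_pcoa_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        labels = tuple(f"s{i}" for i in range(6))
        coords, explained = popgen.classical_mds(PairwiseMatrix(labels, d))
        c = coords.to_numpy()
        d2 = np.linalg.norm(c[:, None] - c[None], axis=2)
        assert np.allclose(d, d2, atol=1e-8)
        assert np.all(np.diff(explained) <= 1e-12)

    def test_nj_three_taxa_closed_form(self):
        import skbio
        d_ab, d_ac, d_bc = 0.4, 0.6, 0.8
        m = np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]])
        dm = skbio.DistanceMatrix(m, ids=["a", "b", "c"])
        tree = skbio.tree.nj(dm)
        tips = {t.name: t.length for t in tree.tips()}
        assert tips["a"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert tips["b"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert tips["c"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_nj_newick_contains_each_sample_once(self):
        rng = np.random.default_rng(2)
        panel = make_panel({"A": 2, "B": 2})
        m = make_genotypes(rng.integers(0, 3, size=(30, 4)), panel.sample_ids)
        nwk = popgen.nj_tree(m, panel)
        import skbio
        from io import StringIO
        tree = skbio.TreeNode.read(StringIO(nwk))
        names = sorted(t.name for t in tree.tips())
        assert names == sorted(panel.sample_ids)
        assert all((t.length or 0) >= 0 for t in tree.traverse())


class TestIbsDistance:
    def test_identical_zero_opposite_one(self):
        panel = make_panel({"P": 3})
        d = np.array([[0, 0, 2], [2, 2, 0], [1, 1, 1]])
        m = make_genotypes(d, panel.sample_ids)
        dist = popgen.ibs_distance(m)
        assert dist.matrix[0, 1] == pytest.approx(0.0)
        # s1=(0,2,1) vs s3=(2,0,1): IBS per locus 0, 0, 1 -> distance 2/3
        assert dist.matrix[0, 2] == pytest.approx(2 / 3)
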