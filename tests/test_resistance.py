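"""Herbicide target-gene analysis: alignment filter, Fisher tests, codons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from ambropop import resistance as res
from ambropop.datatypes import ExpressionMatrix, TranscriptCollection
from ambropop.simulate import default_catalog
from ambropop.unique import revcomp
from conftest import make_genotypes, make_panel


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindTargetGenes:
    def test_identical_query_perfect_hit(self):
        rng = np.random.default_rng(0)
        seq = rand_seq(rng, 400)
        ref = TranscriptCollection({"r1": seq, "r2": rand_seq(rng, 400)})
        hits = res.find_target_genes(ref, TranscriptCollection({"q": seq},
                                                               "queries"))
        assert len(hits) == 1
        row = hits.iloc[0]
        assert row["reference"] == "r1"
        assert row["identity"] == pytest.approx(1.0)
        assert row["coverage"] == pytest.approx(1.0)

    def test_reverse_strand_hit_found(self):
        rng = np.random.default_rng(1)
        seq = rand_seq(rng, 300)
        ref = TranscriptCollection({"r1": seq})
        hits = res.find_target_genes(ref, TranscriptCollection(
            {"q": revcomp(seq)}, "queries"))
        assert len(hits) == 1 and hits.iloc[0]["strand"] == "-"

    def test_scattered_mismatches_rejected(self):
        rng = np.random.default_rng(2)
        orig = rand_seq(rng, 400)
        mut = list(orig)
        for i in rng.choice(400, size=60, replace=False):  # 15 % mismatches
            mut[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[i]]
        ref = TranscriptCollection({"r1": "".join(mut)})
        hits = res.find_target_genes(
            ref, TranscriptCollection({"q": orig}, "queries"))
        assert hits.empty

    def test_insufficient_coverage_rejected(self):
        rng = np.random.default_rng(3)
        core = rand_seq(rng, 356)
        tail = rand_seq(rng, 44)  # 11 % of the query has no counterpart
        ref = TranscriptCollection({"r1": core})
        hits = res.find_target_genes(ref, TranscriptCollection(
            {"q": core + tail}, "queries"))
        assert hits.empty


class TestExpressionCompare:
    def test_identical_distributions(self):
        panel = make_panel({"W": 3, "X": 3},
                           habitats={"W": "weedy", "X": "wild"})
        expr = ExpressionMatrix(pd.DataFrame(
            [[1, 2, 3, 1, 2, 3]], index=["t1"], columns=panel.sample_ids,
            dtype=float))
        out = res.expression_compare(expr, panel, {"G": ["t1"]})
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_complete_separation_significant(self):
        panel = make_panel({"W": 20, "X": 20},
                           habitats={"W": "weedy", "X": "wild"})
        vals = list(np.linspace(100, 200, 20)) + list(np.linspace(1, 5, 20))
        expr = ExpressionMatrix(pd.DataFrame([vals], index=["t1"],
                                             columns=panel.sample_ids))
        out = res.expression_compare(expr, panel, {"G": ["t1"]})
        assert out.iloc[0]["median_log2_weedy"] > out.iloc[0]["median_log2_wild"]
        assert out.iloc[0]["p"] < 0.01

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        panel = make_panel({"W": 4, "X": 4},
                           habitats={"W": "weedy", "X": "wild"})
        vals = rng.lognormal(3, 1, size=(2, 8))
        expr = ExpressionMatrix(pd.DataFrame(
            vals, index=["t1", "t2"], columns=panel.sample_ids))
        perm = list(rng.permutation(panel.sample_ids))
        out1 = res.expression_compare(expr, panel, {"G": ["t1", "t2"]})
        out2 = res.expression_compare(
            ExpressionMatrix(expr.values[perm]), panel, {"G": ["t1", "t2"]})
        pd.testing.assert_frame_equal(out1, out2)


class TestFisherTwoSided:
    def test_independence_table(self):
        assert res.fisher_exact_two_sided(((10, 10), (10, 10))) == 1.0

    def test_diagonal_table_closed_form(self):
        # [[5,0],[0,5]]: only the two extreme tables are as unlikely
        assert res.fisher_exact_two_sided(((5, 0), (0, 5))) == \
            pytest.approx(2 / math.comb(10, 5), abs=1e-15)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            t = tuple(tuple(int(x) for x in row)
                      for row in rng.integers(0, 15, size=(2, 2)))
            ours = res.fisher_exact_two_sided(t)
            scipys = fisher_exact(t, "two-sided")[1]
            assert ours == pytest.approx(scipys, rel=1e-7, abs=1e-12)


class TestSnpAlleleFreq:
    def test_allele_counting(self):
        panel = make_panel({"W": 3, "X": 3},
                           habitats={"W": "weedy", "X": "wild"})
        # weedy genotypes 0/0, 0/1, 1/1 -> alt frequency 3/6 = 0.5
        m = make_genotypes(np.array([[0, 1, 2, 0, 0, 0]]), panel.sample_ids)
        out = res.snp_allele_freq_test(m, panel)
        assert out.iloc[0]["freq_weedy"] == pytest.approx(0.5)
        assert out.iloc[0]["freq_wild"] == 0.0

    def test_monomorphic_p_one(self):
        panel = make_panel({"W": 3, "X": 3},
                           habitats={"W": "weedy", "X": "wild"})
        m = make_genotypes(np.zeros((1, 6), dtype=int), panel.sample_ids)
        out = res.snp_allele_freq_test(m, panel)
        assert out.iloc[0]["p"] == 1.0

    def test_gene_region_restriction(self):
        panel = make_panel({"W": 2, "X": 2},
                           habitats={"W": "weedy", "X": "wild"})
        import pandas as pd
        loci = pd.DataFrame({"chrom": ["c1", "c2"], "pos": [1, 1],
                             "ref": "A", "alt": "T"})
        from ambropop.datatypes import GenotypeMatrix
        m = GenotypeMatrix(loci, panel.sample_ids,
                           np.zeros((2, 4), dtype=np.int8))
        out = res.snp_allele_freq_test(m, panel, gene_region="c2")
        assert list(out["chrom"]) == ["c2"]


class TestCodonAnnotation:
    def _als(self):
        from ambropop.simulate import (SimulationConfig, simulate_panel,
                                       simulate_transcripts)
        cfg = SimulationConfig(seed=0, n_reference_transcripts=5)
        panel = simulate_panel(cfg)
        ref, _, truth = simulate_transcripts(cfg, panel)
        return ref["TR_ALS"], truth["als_orf_start"], truth["als_snps"]

    def test_trp_574_leu_known_resistance(self):
        seq, start, snps = self._als()
        snp = snps[snps["snp_id"] == "ALS_W574c2"]
        changes = res.annotate_codon_changes(seq, start, 620 * 3, snp,
                                             default_catalog())
        ch = changes[0]
        assert (ch.ref_codon, ch.alt_codon) == ("TGG", "TTG")
        assert (ch.ref_aa, ch.alt_aa) == ("W", "L")
        assert ch.known_resistance
        assert ch.classification == "nonconservative"

    def test_pro_197_joint_double_mutation_gives_phe(self):
        seq, start, snps = self._als()
        both = snps[snps["snp_id"].isin(["ALS_P197c1", "ALS_P197c2"])]
        changes = res.annotate_codon_changes(seq, start, 620 * 3, both,
                                             default_catalog())
        ch = changes[0]
        assert (ch.ref_codon, ch.alt_codon) == ("CCT", "TTT")
        assert (ch.ref_aa, ch.alt_aa) == ("P", "F")
        assert ch.known_resistance
        # joint application differs from either single effect (Ser / Leu)
        singles = [res.annotate_codon_changes(seq, start, 620 * 3,
                                              snps[snps["snp_id"] == sid],
                                              default_catalog())[0].alt_aa
                   for sid in ("ALS_P197c1", "ALS_P197c2")]
        assert singles == ["S", "L"]
        assert ch.alt_aa not in singles

    def test_synonymous_change(self):
        seq = "ATG" + "GCT" + "TAA"  # M A stop
        snp = pd.DataFrame({"pos": [6], "ref": ["T"], "alt": ["C"]})
        ch = res.annotate_codon_changes(seq, 0, 9, snp, default_catalog())[0]
        assert (ch.ref_codon, ch.alt_codon) == ("GCT", "GCC")
        assert ch.classification == "synonymous"

    def test_snp_outside_orf_reported_non_coding(self):
        seq = "CCCC" + "ATGGCTTAA"
        snp = pd.DataFrame({"pos": [2], "ref": ["C"], "alt": ["T"]})
        ch = res.annotate_codon_changes(seq, 4, 9, snp, default_catalog())[0]
        assert ch.classification == "non_coding"

    def test_full_codon_table_matches_standard_code(self):
        # frozen standard genetic code, written out independently
        bases = "TCAG"
        aas = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
               "VVVVAAAADDEEGGGG")
        code = {}
        i = 0
        for b1 in bases:
            for b2 in bases:
                for b3 in bases:
                    code[b1 + b2 + b3] = aas[i]
                    i += 1
        from Bio.Seq import Seq
        for codon, aa in code.items():
            assert str(Seq(codon).translate()) == aa


class TestGenotypeTally:
    def test_all_reference_homozygous(self):
        panel = make_panel({"W": 4, "X": 3},
                           habitats={"W": "weedy", "X": "wild"})
        m = make_genotypes(np.zeros((1, 7), dtype=int), panel.sample_ids)
        out = res.genotype_tally(m, panel, [("c1", 1)])
        w = out[out["habitat"] == "weedy"].iloc[0]
        assert (w["n_00"], w["n_01"], w["n_11"]) == (4, 0, 0)

    def test_tallies_conserve_sample_counts(self):
        rng = np.random.default_rng(6)
        panel = make_panel({"W": 5, "X": 5},
                           habitats={"W": "weedy", "X": "wild"})
        d = rng.integers(0, 3, size=(3, 10)).astype(np.int8)
        d[0, 2] = -1
        m = make_genotypes(d, panel.sample_ids)
        out = res.genotype_tally(m, panel, [("c1", i) for i in (1, 2, 3)])
        for _, row in out.iterrows():
            assert row["n_00"] + row["n_01"] + row["n_11"] + \
                row["n_missing"] == 5

    def test_carrier_fraction_recovery(self, bundle):
        cfg = bundle.config
        snps = bundle.truth["als_snps"]
        panel = bundle.panel.drop_replicate_duplicates()
        m = bundle.genotypes.subset_samples(panel.sample_ids)
        out = res.genotype_tally(m, panel,
                                 [(r.chrom, r.pos) for r in
                                  snps.itertuples(index=False)])
        for habitat in ("weedy", "wild"):
            sub = out[out["habitat"] == habitat]
            n = (sub[["n_00", "n_01", "n_11"]].sum(axis=1)).iloc[0]
            frac = cfg.als_resistance_carrier_fraction[habitat]
            carriers = sub["carrier_freq"].mean()
            se = np.sqrt(frac * (1 - frac) / n)
            assert abs(carriers - frac) < 4 * se + 0.02
            # resistance genotypes present in BOTH habitats
            assert (sub["n_01"] + sub["n_11"]).sum() > 0
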