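"""Generator contracts: design emulation, determinism, parameter recovery."""

import numpy as np
import pytest

from ambropop import popgen
from ambropop.popgen import haversine_km
from ambropop.simulate import (RegionConfig, SimulationConfig, adjacent_pairs,
                               simulate_bundle, simulate_expression,
                               simulate_genotypes, simulate_panel,
                               simulate_transcripts)


def two_pop_config(f: float, seed: int, n_loci: int = 2000,
                   n: int = 20) -> SimulationConfig:
    """One region, one weedy + one wild population drifting independently."""
    return SimulationConfig(
        seed=seed, n_loci=n_loci, samples_per_pop=(n, n),
        fst_between_regions=0.0, n_replicate_pairs=0,
        regions=(RegionConfig("R", n_weedy_pops=1, n_wild_pops=1,
                              fst_within=f, ibd=False),))


class TestPanel:
    def test_default_design(self):
        panel = simulate_panel(SimulationConfig(seed=0))
        assert len(panel.populations) == 20
        assert set(panel.table["region"]) == {"OH", "IAMN"}
        for region in ("OH", "IAMN"):
            sub = panel.table[panel.table["region"] == region]
            pops = sub.groupby("population_id")["habitat"].first()
            assert (pops == "weedy").sum() == 4
            assert (pops == "wild").sum() == 6

    def test_population_sizes_in_range(self):
        panel = simulate_panel(SimulationConfig(seed=1))
        sizes = panel.table.groupby("population_id").size()
        assert sizes.between(2, 5).all()

    def test_at_least_two_adjacent_pairs_within_100m(self):
        panel = simulate_panel(SimulationConfig(seed=2))
        cent = panel.table.groupby("population_id").agg(
            habitat=("habitat", "first"), lat=("latitude", "mean"),
            lon=("longitude", "mean"))
        close = 0
        for wp, wrow in cent[cent["habitat"] == "weedy"].iterrows():
            for xp, xrow in cent[cent["habitat"] == "wild"].iterrows():
                d = haversine_km(wrow["lat"], wrow["lon"],
                                 xrow["lat"], xrow["lon"])
                close += d < 0.1
        assert close >= 2

    def test_same_seed_identical_panel(self):
        a = simulate_panel(SimulationConfig(seed=9)).table
        b = simulate_panel(SimulationConfig(seed=9)).table
        assert a.equals(b)

    def test_adjacent_pairs_match_habitat_and_region(self):
        panel = simulate_panel(SimulationConfig(seed=0))
        pairs = adjacent_pairs(panel)
        assert len(pairs) == 8
        for row in pairs.itertuples(index=False):
            assert panel.habitat_of(row.weedy_pop) == "weedy"
            assert panel.habitat_of(row.wild_pop) == "wild"
            assert panel.region_of(row.weedy_pop) == row.region


class TestGenotypes:
    def test_fst_zero_everywhere_copies_ancestral(self):
        cfg = two_pop_config(0.0, seed=3, n_loci=50, n=4)
        panel = simulate_panel(cfg)
        _, truth = simulate_genotypes(cfg, panel)
        freqs = truth["pop_freqs"]
        np.testing.assert_allclose(freqs.iloc[:, 0], freqs.iloc[:, 1])

    def test_wc_recovery_at_f005(self):
        # Monte-Carlo check of the estimator against the generative parameter
        ests = []
        for seed in range(6):
            cfg = two_pop_config(0.05, seed=seed)
            panel = simulate_panel(cfg)
            m, _ = simulate_genotypes(cfg, panel)
            pops = panel.populations
            ests.append(popgen.wc_fst(m, panel, pops[0], pops[1]))
        assert abs(np.mean(ests) - 0.05) < 0.02

    def test_replicate_pair_differs_at_exactly_noise_loci(self):
        cfg = SimulationConfig(seed=4, n_loci=500)
        panel = simulate_panel(cfg)
        m, truth = simulate_genotypes(cfg, panel)
        for group, members in panel.replicate_groups().items():
            idx = m.sample_index(members)
            diff = int((m.dosage[:, idx[0]] != m.dosage[:, idx[1]]).sum())
            assert diff == cfg.replicate_noise_snps
        assert len(truth["replicate_discordant"]) == \
            cfg.replicate_noise_snps * len(panel.replicate_groups())

    def test_same_seed_identical_matrix(self):
        cfg = SimulationConfig(seed=5, n_loci=100)
        panel = simulate_panel(cfg)
        a, _ = simulate_genotypes(cfg, panel)
        b, _ = simulate_genotypes(cfg, panel)
        assert a.equals(b)


class TestExpression:
    def test_null_config_shows_no_habitat_direction_bias(self):
        # no planted differences: either habitat may have the higher CV median
        from ambropop.ged import compare_ged_groups, ged_cv
        higher = []
        for seed in range(8):
            cfg = SimulationConfig(seed=seed, n_transcripts=400,
                                   ged_inflation_wild=1.0, n_ged_genes=0,
                                   n_de_genes_per_pair=0, n_modules=0)
            panel = simulate_panel(cfg)
            expr, _ = simulate_expression(cfg, panel)
            table = ged_cv(expr, panel, "by_habitat_within_region")
            cw = table.loc[table["group_id"] == "OH:weedy", "cv"]
            cx = table.loc[table["group_id"] == "OH:wild", "cv"]
            _, p, h = compare_ged_groups(cw, cx)
            higher.append(h)
        assert {"weedy", "wild"} >= set(higher)
        assert len(set(higher)) > 1  # not systematically one-sided

    def test_planted_module_correlation_structure(self):
        cfg = SimulationConfig(seed=6, n_transcripts=300, n_modules=2,
                               rewired_module_count=0, n_ged_genes=0,
                               n_de_genes_per_pair=0,
                               module_size_range=(40, 40))
        panel = simulate_panel(cfg)
        expr, truth = simulate_expression(cfg, panel)
        modules = truth["modules"].set_index("transcript_id")["module_weedy"]
        x = np.log2(expr.values.to_numpy() + 1)
        cor = np.abs(np.corrcoef(x))
        in1 = np.nonzero((modules == 1).to_numpy())[0]
        out = np.nonzero((modules == 0).to_numpy())[0][:40]
        within = cor[np.ix_(in1, in1)][np.triu_indices(len(in1), 1)].mean()
        between = cor[np.ix_(in1, out)].mean()
        assert within > between + 0.2

    def test_same_seed_identical_matrix(self):
        cfg = SimulationConfig(seed=7, n_transcripts=400, n_ged_genes=20,
                               n_de_genes_per_pair=10, n_modules=2)
        panel = simulate_panel(cfg)
        a, _ = simulate_expression(cfg, panel)
        b, _ = simulate_expression(cfg, panel)
        assert a.values.equals(b.values)

    def test_undersized_matrix_rejected(self):
        cfg = SimulationConfig(seed=7, n_transcripts=100)
        panel = simulate_panel(cfg)
        with pytest.raises(ValueError, match="planted structure"):
            simulate_expression(cfg, panel)


class TestTranscripts:
    def test_als_codons_and_574_mutation(self):
        cfg = SimulationConfig(seed=8)
        panel = simulate_panel(cfg)
        reference, _, truth = simulate_transcripts(cfg, panel)
        seq = reference["TR_ALS"]
        start = truth["als_orf_start"]
        codon197 = seq[start + 196 * 3: start + 197 * 3]
        codon574 = seq[start + 573 * 3: start + 574 * 3]
        assert codon197 == "CCT" and codon574 == "TGG"
        snp = truth["als_snps"].set_index("snp_id").loc["ALS_W574c2"]
        # G>T at the codon's second position turns TGG into TTG
        assert seq[snp.pos - 1] == "G" and snp.alt == "T"
        assert snp.pos == start + 573 * 3 + 2

    def test_planted_uniques_below_containment_threshold(self):
        from ambropop.unique import collection_kmers, containment
        cfg = SimulationConfig(seed=9, n_reference_transcripts=30,
                               n_unique_transcripts_per_pop=5)
        panel = simulate_panel(cfg)
        reference, colls, truth = simulate_transcripts(cfg, panel)
        pairs = truth["pairs"].set_index("weedy_pop")["wild_pop"]
        pop = pairs.index[0]
        paired = colls[pairs[pop]]
        pk = collection_kmers(paired)
        for row in truth["unique_transcripts"].itertuples(index=False):
            if row.population_id != pop:
                continue
            assert containment(colls[pop][row.transcript_id], pk) < 0.6

    def test_same_seed_identical_sequences(self):
        cfg = SimulationConfig(seed=10, n_reference_transcripts=20)
        panel = simulate_panel(cfg)
        a = simulate_transcripts(cfg, panel)[0]
        b = simulate_transcripts(cfg, panel)[0]
        assert a.entries == b.entries


class TestBundle:
    def test_bundle_truth_covers_downstream_scoring(self, bundle):
        for key in ("replicate_discordant", "unique_transcripts",
                    "weedy_families", "als_snps", "modules", "ged_genes",
                    "de_genes", "pairwise_fst_true"):
            assert key in bundle.truth

    def test_bundle_write_is_deterministic(self, small_config, tmp_path):
        import hashlib
        from ambropop.simulate import write_bundle

        def digest(d):
            h = hashlib.sha256()
            for p in sorted(d.rglob("*")):
                if p.is_file():
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
            return h.hexdigest()

        write_bundle(simulate_bundle(small_config), tmp_path / "a")
        write_bundle(simulate_bundle(small_config), tmp_path / "b")
        assert digest(tmp_path / "a") == digest(tmp_path / "b")
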