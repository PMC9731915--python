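"""End-to-end orchestration: replicate filter -> population genetics -> GED
-> co-expression networks -> unique transcripts -> herbicide genes ->
enrichment, with a machine-readable run manifest.

Outputs are deterministic functions of (inputs, seed): running twice with the
same seed produces byte-identical files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, enrich as enrich_mod, ged as ged_mod, io as aio
from . import network as net_mod, popgen, resistance as res_mod, unique as uniq_mod
from .simulate import SimulationConfig, simulate_bundle, write_bundle

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds of the analysis, defaulting to the study's values."""

    seed: int = 0
    map_threshold: float = 0.8       # unique-transcript containment cutoff
    min_orf_aa: int = 100
    sim_threshold: float = 0.5       # homolog protein k-mer similarity
    beta: float = 6.0                # soft power
    min_module_size: int = 30
    cut_height: float = 0.97
    min_identity: float = 0.90       # herbicide gene hits
    min_coverage: float = 0.90
    alpha: float = 0.05              # BH-adjusted enrichment / DE cutoff
    mantel_permutations: int = 999
    band_significant: float = 30.0   # -log10 p module conservation bands
    band_moderate: float = 5.0


REQUIRED_INPUTS = ("panel", "vcf", "expression", "reference", "annotation",
                   "catalog", "queries", "pairs")


def _require(input_dir: Path, names: dict[str, str]) -> dict[str, Path]:
    paths = {}
    for key, fname in names.items():
        p = input_dir / fname
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")
        paths[key] = p
    return paths


def run_pipeline(config: PipelineConfig, input_dir: str | Path | None,
                 out_dir: str | Path,
                 simulate: SimulationConfig | None = None) -> dict:
    """Run every stage and write a report bundle plus a JSON manifest.

    Either ``input_dir`` contains a complete input bundle or ``simulate``
    supplies a generator config (the bundle is generated into
    ``out_dir/inputs``). Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    if simulate is not None:
        bundle = simulate_bundle(simulate)
        input_dir = out / "inputs"
        write_bundle(bundle, input_dir)
    if input_dir is None:
        raise ValueError("either input_dir or simulate must be given")
    input_dir = Path(input_dir)
    paths = _require(input_dir, {
        "panel": "panel.tsv", "vcf": "genotypes.vcf",
        "expression": "expression.tsv", "reference": "reference.fasta",
        "annotation": "annotation.tsv", "catalog": "resistance_catalog.tsv",
        "queries": "herbicide_queries.fasta", "pairs": "pairs.tsv"})

    panel = aio.read_panel(paths["panel"])
    genotypes = aio.read_vcf(paths["vcf"], panel)
    expression = aio.read_expression(paths["expression"])
    reference = aio.read_fasta(paths["reference"])
    annotation = aio.read_annotation(paths["annotation"])
    catalog = aio.read_catalog(paths["catalog"])
    queries = aio.read_fasta(paths["queries"], label="queries")
    pairs = pd.read_csv(paths["pairs"], sep="\t")
    pop_fastas = {p.stem: aio.read_fasta(p, label=p.stem)
                  for p in sorted((input_dir / "transcripts").glob("*.fasta"))}

    manifest: dict = {
        "package": "ambropop", "version": __version__,
        "seed": config.seed,
        "thresholds": asdict(config),
        "inputs": {k: str(Path(v).name) for k, v in paths.items()},
        "stages": [],
        "notes": ["sample tree built with neighbor-joining on 1-IBS distance "
                  "(substitution for approximate-ML phylogenetics)"],
    }

    def stage(name: str, **info) -> None:
        log.info("stage %s done", name)
        manifest["stages"].append({"name": name, **info})

    # 1. replicate-concordance filter
    filtered, removed = popgen.replicate_concordance_filter(genotypes, panel)
    removed.to_csv(out / "removed_discordant_loci.tsv", sep="\t", index=False)
    stage("filter", loci_in=genotypes.n_loci, loci_out=filtered.n_loci,
          removed=len(removed))

    # replicates are repeat libraries of single plants: once the concordance
    # filter has used them, keep one library per plant for every analysis
    panel = panel.drop_replicate_duplicates()
    filtered = filtered.subset_samples(panel.sample_ids)
    expression = expression.subset_samples(
        [s for s in panel.sample_ids if s in expression.sample_ids])
    stage("dedup_replicates", samples=len(panel.sample_ids))

    # 2. population genetics
    div = popgen.diversity_table(filtered, panel)
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    fst = popgen.pairwise_fst(filtered, panel)
    fst.to_frame().to_csv(out / "fst.tsv", sep="\t")
    km = popgen.geographic_distance(panel)
    km.to_frame().to_csv(out / "distances_km.tsv", sep="\t")
    mantel = {}
    for region in sorted(set(panel.table["region"])):
        pops = [p for p in fst.labels if panel.region_of(p) == region]
        if len(pops) < 4:
            continue
        idx = [fst.labels.index(p) for p in pops]
        sub_f = type(fst)(tuple(pops), fst.matrix[np.ix_(idx, idx)], "fst")
        kidx = [km.labels.index(p) for p in pops]
        sub_k = type(km)(tuple(pops), km.matrix[np.ix_(kidx, kidx)], "km")
        r, p = popgen.mantel_test(sub_f, sub_k,
                                  n_perm=config.mantel_permutations,
                                  seed=config.seed)
        mantel[region] = {"r": r, "p": p,
                          "n_perm": config.mantel_permutations,
                          "seed": config.seed}
    (out / "mantel.json").write_text(json.dumps(mantel, indent=2, sort_keys=True))
    coords, explained = popgen.pcoa(filtered, panel)
    coords.to_csv(out / "pcoa.tsv", sep="\t", index_label="sample_id")
    (out / "tree.nwk").write_text(popgen.nj_tree(filtered, panel) + "\n")
    stage("popgen", populations=len(div), mantel=mantel,
          pcoa_axes=int(coords.shape[1]))

    # 3. gene expression diversity
    ged_table = ged_mod.ged_cv(expression, panel, "by_population")
    ged_table.to_csv(out / "ged.tsv", sep="\t", index=False)
    region_tests = {}
    hr = ged_mod.ged_cv(expression, panel, "by_habitat_within_region")
    for region in sorted(set(panel.table["region"])):
        cw = hr.loc[hr["group_id"] == f"{region}:weedy", "cv"]
        cx = hr.loc[hr["group_id"] == f"{region}:wild", "cv"]
        if cw.empty or cx.empty:
            continue
        s, p, higher = ged_mod.compare_ged_groups(cw, cx)
        region_tests[region] = {"statistic": s, "p": p, "higher_median": higher}
    (out / "ged_region_tests.json").write_text(
        json.dumps(region_tests, indent=2, sort_keys=True))
    twofold_rows = []
    de_sets = {}
    for row in pairs.itertuples(index=False):
        flags = ged_mod.pairwise_twofold_ged(
            expression, panel, (row.weedy_pop, row.wild_pop), seed=config.seed)
        for direction, ids in flags.items():
            for tid in ids:
                twofold_rows.append((row.weedy_pop, row.wild_pop, direction,
                                     tid))
        de = ged_mod.de_rank_test(expression, panel,
                                  (row.weedy_pop, row.wild_pop),
                                  alpha=config.alpha)
        de_sets[row.weedy_pop] = (set(de["up"]), set(de["down"]))
    pd.DataFrame(twofold_rows, columns=["weedy_pop", "wild_pop", "direction",
                                        "transcript_id"]) \
        .to_csv(out / "ged_twofold.tsv", sep="\t", index=False)
    if len(de_sets) >= 2:
        ged_mod.deg_overlap(de_sets).to_csv(out / "deg_overlap.tsv", sep="\t",
                                            index=False)
    stage("ged", pairs=len(pairs), region_tests=region_tests,
          twofold_flags=len(twofold_rows))

    # 4. co-expression networks and module conservation
    part_w = net_mod.build_habitat_network(
        expression, panel, "weedy", beta=config.beta,
        min_size=config.min_module_size, cut_height=config.cut_height)
    part_x = net_mod.build_habitat_network(
        expression, panel, "wild", beta=config.beta,
        min_size=config.min_module_size, cut_height=config.cut_height)
    pd.DataFrame({"transcript_id": part_w.assignment.index,
                  "module_weedy": part_w.assignment.to_numpy(),
                  "module_wild": part_x.assignment.reindex(
                      part_w.assignment.index).fillna(0).astype(int).to_numpy()
                  }).to_csv(out / "modules.tsv", sep="\t", index=False)
    classification = net_mod.module_overlap_classify(part_w, part_x)
    classification.overlap.to_csv(out / "module_overlap.tsv", sep="\t",
                                  index=False)
    classification.classes.to_csv(out / "module_classes.tsv", sep="\t",
                                  index=False)
    stage("network", modules_weedy=part_w.n_modules,
          modules_wild=part_x.n_modules,
          class_counts=classification.class_counts.to_dict())

    # 5. unique transcripts
    uniq_dir = out / "unique"
    uniq_dir.mkdir(exist_ok=True)
    uniques: dict[str, "object"] = {}
    pair_of = {}
    for row in pairs.itertuples(index=False):
        pair_of[row.weedy_pop] = row.wild_pop
        pair_of.setdefault(row.wild_pop, row.weedy_pop)
    for pop, coll in pop_fastas.items():
        if pop not in pair_of or pair_of[pop] not in pop_fastas:
            continue
        uniq = uniq_mod.extract_unique(coll, reference,
                                       pop_fastas[pair_of[pop]],
                                       map_threshold=config.map_threshold)
        uniq, _ = uniq_mod.orf_filter(uniq, min_aa=config.min_orf_aa)
        uniques[pop] = uniq
        aio.write_fasta(uniq, uniq_dir / f"{pop}_unique.fasta")
    shared_terms = {}
    group_rows = []
    weedy_terms_by_region: dict[str, set[str]] = {}
    wild_terms_all: set[str] = set()
    regions = sorted(set(panel.table["region"]))
    for habitat in ("weedy", "wild"):
        for region in regions:
            pops = [p for p in uniques
                    if panel.region_of(p) == region
                    and panel.habitat_of(p) == habitat]
            if len(pops) < 2:
                continue
            groups = uniq_mod.homolog_grouping(
                {p: uniques[p] for p in pops},
                sim_threshold=config.sim_threshold,
                min_aa=config.min_orf_aa)
            shared = uniq_mod.shared_by_all(groups, pops)
            for g in shared:
                for pop, tid in g.members:
                    group_rows.append((habitat, region, g.group_id, pop, tid))
            terms = uniq_mod.group_terms(shared, annotation)
            shared_terms[f"{habitat}:{region}"] = sorted(terms)
            if habitat == "weedy":
                weedy_terms_by_region[region] = terms
            else:
                wild_terms_all |= terms
    pd.DataFrame(group_rows, columns=["habitat", "region", "group_id",
                                      "population_id", "transcript_id"]) \
        .to_csv(out / "homolog_groups.tsv", sep="\t", index=False)
    weedy_shared = set.intersection(*weedy_terms_by_region.values()) \
        if weedy_terms_by_region else set()
    term_report = {
        "shared_terms": shared_terms,
        "weedy_shared_across_regions": sorted(weedy_shared),
        "weedy_specific": sorted(weedy_shared - wild_terms_all),
    }
    (out / "unique_terms.json").write_text(
        json.dumps(term_report, indent=2, sort_keys=True))
    stage("unique", populations=len(uniques),
          uniques_per_pop={p: len(c) for p, c in sorted(uniques.items())},
          weedy_shared_terms=len(weedy_shared))

    # 6. herbicide target genes
    hits = res_mod.find_target_genes(reference, queries,
                                     min_identity=config.min_identity,
                                     min_coverage=config.min_coverage)
    hits.to_csv(out / "herbicide_hits.tsv", sep="\t", index=False)
    codon_rows = []
    if not hits.empty:
        gene_transcripts = {q: list(sub["reference"])
                            for q, sub in hits.groupby("query")}
        res_mod.expression_compare(expression, panel, gene_transcripts) \
            .to_csv(out / "herbicide_expression.tsv", sep="\t", index=False)
        for ref_name in sorted(set(hits["reference"])):
            snp_tests = res_mod.snp_allele_freq_test(filtered, panel,
                                                     gene_region=ref_name,
                                                     alpha=config.alpha)
            if snp_tests.empty:
                continue
            snp_tests.to_csv(out / f"herbicide_snps_{ref_name}.tsv", sep="\t",
                             index=False)
            orf = uniq_mod.longest_orf(reference[ref_name])
            if orf is None or orf.strand != "+":
                continue
            changes = res_mod.annotate_codon_changes(
                reference[ref_name], orf.start, orf.aa_length * 3,
                snp_tests[["pos", "ref", "alt"]], catalog, gene="ALS")
            for ch in changes:
                codon_rows.append((ref_name,
                                   ";".join(map(str, ch.positions)),
                                   ch.codon_number, ch.ref_codon, ch.alt_codon,
                                   ch.ref_aa, ch.alt_aa, ch.classification,
                                   ch.known_resistance))
            tal = res_mod.genotype_tally(
                filtered, panel,
                [(ref_name, p) for p in snp_tests["pos"]])
            tal.to_csv(out / f"herbicide_tally_{ref_name}.tsv", sep="\t",
                       index=False)
    pd.DataFrame(codon_rows, columns=["transcript", "positions", "codon",
                                      "ref_codon", "alt_codon", "ref_aa",
                                      "alt_aa", "classification",
                                      "known_resistance"]) \
        .to_csv(out / "codon_changes.tsv", sep="\t", index=False)
    stage("herbicide", hits=len(hits), codon_changes=len(codon_rows))

    # 7. enrichment on the wild-higher twofold GED flags (example call site:
    # background = all transcripts in the expression matrix)
    flagged = sorted({t for (_, _, d, t) in twofold_rows if d == "wild_higher"})
    background = list(expression.values.index)
    enr = enrich_mod.enrich(flagged, background, annotation,
                            alpha=config.alpha)
    enr.to_csv(out / "enrichment_wild_higher.tsv", sep="\t", index=False)
    stage("enrich", gene_set=len(flagged),
          significant_terms=int(enr["significant"].sum()) if len(enr) else 0)

    # wall time is logged but kept out of the manifest: reruns with one seed
    # must be byte-identical
    log.info("pipeline finished in %.1f s", time.monotonic() - t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
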