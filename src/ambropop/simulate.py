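"""Synthetic study generator: paired weedy/wild population transcriptomics.

Emulates the sampling design and the statistical structure the downstream
analyses assume: ~20 populations in 2 regions with 2-5 plants each, adjacent
weedy/wild pairs within 100 m, hierarchical allele-frequency drift
(Balding-Nichols between regions; a stepping-stone chain inside the region
flagged for isolation by distance), TPM expression with habitat-dependent
dispersion, planted differentially expressed genes and co-expression modules
(some rewired between habitats), population-unique transcripts with
cross-population homolog families, an ALS-like herbicide-target transcript
carrying the canonical codon-197/574 resistance alleles in both habitats,
and biological replicate pairs sharing true SNPs plus injected discordant
calls.

Every generator is a pure function of (config, seed): reruns are
bit-identical, and truth tables score each downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .datatypes import (ExpressionMatrix, GenotypeMatrix, PairwiseMatrix,
                        ResistanceCatalog, SamplePanel, TranscriptCollection)
from .popgen import haversine_km
from .unique import longest_orf

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RegionConfig:
    name: str
    n_weedy_pops: int = 4
    n_wild_pops: int = 6
    fst_within: float = 0.01   # per-step drift along the transect
    ibd: bool = False
    center_lat: float = 40.0
    center_lon: float = -83.0


@dataclass
class SimulationConfig:
    """Defaults mirror the study design: 2 regions x (4 weedy + 6 wild)
    populations, 2-5 plants per population, differentiation on the
    0.002-0.109 FST scale, wild dispersion twice weedy on the flagged genes."""

    seed: int = 0
    regions: tuple[RegionConfig, ...] = (
        RegionConfig("OH", ibd=True, center_lat=40.0, center_lon=-83.0),
        RegionConfig("IAMN", ibd=False, center_lat=43.0, center_lon=-93.0),
    )
    fst_between_regions: float = 0.05
    samples_per_pop: tuple[int, int] = (2, 5)
    n_loci: int = 2000
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    # expression
    n_transcripts: int = 3000
    n_modules: int = 4
    module_size_range: tuple[int, int] = (35, 60)
    rewired_module_count: int = 2
    module_loading: float = 0.9
    noise_log2_sd_range: tuple[float, float] = (0.4, 0.8)
    pop_effect_sd: float = 0.3
    baseline_log2_mean: float = 4.5
    baseline_log2_sd: float = 1.5
    ged_inflation_wild: float = 2.0
    n_ged_genes: int = 200
    n_de_genes_per_pair: int = 50
    de_log2fc: float = 2.0
    # sequences
    n_reference_transcripts: int = 120
    n_unique_transcripts_per_pop: int = 20
    n_shared_weedy_unique: int = 5
    family_divergence_range: tuple[float, float] = (0.02, 0.05)
    # resistance
    als_resistance_carrier_fraction: dict = field(
        default_factory=lambda: {"weedy": 0.15, "wild": 0.10})
    n_neutral_als_snps: int = 6
    # replicates
    n_replicate_pairs: int = 2
    replicate_noise_snps: int = 25
    # annotation
    n_terms: int = 40

    def __post_init__(self) -> None:
        if not 0 <= self.fst_between_regions < 1:
            raise ValueError("fst_between_regions must be in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must be within (0, 0.5]")
        for frac in self.als_resistance_carrier_fraction.values():
            if not 0 <= frac <= 1:
                raise ValueError("carrier fractions must be in [0, 1]")
        if self.samples_per_pop[0] < 2:
            raise ValueError("populations need >= 2 samples")


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# -------------------------------------------------------------------- panel

def simulate_panel(config: SimulationConfig) -> SamplePanel:
    """Sample panel with populations on a per-region transect.

    Populations are named ``<region><order>-<A|W>`` (A = weedy/agricultural,
    W = wild) by position along the transect; the first two weedy populations
    of each region sit < 100 m from their adjacent wild population (the
    paired-site design), all others are kilometers apart. In regions flagged
    ``ibd`` the genotype generator drifts allele frequencies along this same
    transect so genetic and geographic distance correlate.
    """
    rng = _rng(config, 1)
    rows = []
    replicate_done = 0
    for region in config.regions:
        n_pops = region.n_weedy_pops + region.n_wild_pops
        # interleave weedy among wild along the transect
        habitats = ["wild"] * n_pops
        weedy_slots = np.linspace(1, n_pops - 1, region.n_weedy_pops).astype(int)
        # ensure distinct slots
        weedy_slots = np.unique(weedy_slots)
        extra = iter(i for i in range(n_pops) if i not in set(weedy_slots))
        while len(weedy_slots) < region.n_weedy_pops:
            weedy_slots = np.unique(np.append(weedy_slots, next(extra)))
        for s in weedy_slots:
            habitats[int(s)] = "weedy"
        paired = 0
        for pos in range(n_pops):
            habitat = habitats[pos]
            name = f"{region.name}{pos + 1}-{'A' if habitat == 'weedy' else 'W'}"
            lon = region.center_lon + 0.30 * pos
            lat = region.center_lat + float(rng.normal(0, 0.01))
            # adjacent pair: the wild population right after a weedy one is
            # moved onto the weedy site (< 100 m) for the first two pairs
            if (habitat == "wild" and pos > 0 and habitats[pos - 1] == "weedy"
                    and paired < 2):
                prev = rows[-1]
                lat = prev["latitude"] + 0.0004
                lon = prev["longitude"]
                paired += 1
            n_samples = int(rng.integers(config.samples_per_pop[0],
                                         config.samples_per_pop[1] + 1))
            rep_group = None
            if habitat == "weedy" and replicate_done < config.n_replicate_pairs:
                # replicate = a second library of plant 1, added on top of the
                # plants (capped so the population stays within the size range)
                n_samples = max(2, min(n_samples, config.samples_per_pop[1] - 1))
                rep_group = f"{name}-plant1"
                replicate_done += 1
            for k in range(n_samples):
                rows.append({
                    "sample_id": f"{name}-{k + 1}",
                    "population_id": name,
                    "habitat": habitat,
                    "region": region.name,
                    "latitude": lat,
                    "longitude": lon,
                    "replicate_group": rep_group if (rep_group and k == 0) else pd.NA,
                    "_transect_pos": pos,
                })
            if rep_group:
                rows.append({
                    "sample_id": f"{name}-1b",
                    "population_id": name,
                    "habitat": habitat,
                    "region": region.name,
                    "latitude": lat,
                    "longitude": lon,
                    "replicate_group": rep_group,
                    "_transect_pos": pos,
                })
    table = pd.DataFrame(rows)
    transect = table[["population_id", "_transect_pos", "region"]].drop_duplicates()
    panel = SamplePanel(table.drop(columns="_transect_pos"))
    # stash transect order for the genotype generator (not part of the panel type)
    object.__setattr__(panel, "_transect",
                       dict(zip(transect["population_id"], transect["_transect_pos"])))
    return panel


def adjacent_pairs(panel: SamplePanel) -> pd.DataFrame:
    """Pair each weedy population with the geographically closest wild
    population of its region (the analysis pairing)."""
    cent = panel.table.groupby("population_id", sort=False).agg(
        habitat=("habitat", "first"), region=("region", "first"),
        latitude=("latitude", "mean"), longitude=("longitude", "mean"))
    rows = []
    for pop, row in cent[cent["habitat"] == "weedy"].iterrows():
        wild = cent[(cent["habitat"] == "wild") & (cent["region"] == row["region"])]
        if wild.empty:
            continue
        d = [haversine_km(row["latitude"], row["longitude"], w["latitude"],
                          w["longitude"]) for _, w in wild.iterrows()]
        rows.append((pop, wild.index[int(np.argmin(d))], row["region"]))
    return pd.DataFrame(rows, columns=["weedy_pop", "wild_pop", "region"])


# ---------------------------------------------------------------- genotypes

def _balding_nichols(rng: np.random.Generator, p: np.ndarray,
                     fst: float) -> np.ndarray:
    """Draw drifted allele frequencies around p with differentiation fst."""
    if fst <= 0:
        return p.copy()
    p = np.clip(p, 1e-6, 1 - 1e-6)
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return rng.beta(a, b)


def simulate_genotypes(config: SimulationConfig, panel: SamplePanel
                       ) -> tuple[GenotypeMatrix, dict]:
    """Hierarchical Balding-Nichols genotypes plus replicate noise.

    Ancestral frequencies are uniform on the configured MAF range; each
    region drifts by ``fst_between_regions``; inside an IBD region the
    populations drift sequentially along the transect (a stepping-stone
    chain, ``fst_within`` per step) so divergence grows with separation;
    in a non-IBD region every population drifts independently by
    ``fst_within``. Genotypes are Binomial(2, p_pop). The second member of
    each replicate pair copies the first, then ``replicate_noise_snps``
    discordant singleton calls are injected into it.

    Returns the matrix and a truth dict with keys ``pop_freqs``,
    ``pairwise_fst_true`` (Hudson FST from the latent frequencies) and
    ``replicate_discordant`` (the injected loci).
    """
    rng = _rng(config, 2)
    L = config.n_loci
    lo, hi = config.ancestral_maf_range
    p0 = rng.uniform(lo, hi, size=L)
    transect = getattr(panel, "_transect", None)
    pop_freqs: dict[str, np.ndarray] = {}
    region_names = [r.name for r in config.regions]
    for region in config.regions:
        p_region = _balding_nichols(rng, p0, config.fst_between_regions)
        pops = [p for p in panel.populations if panel.region_of(p) == region.name]
        if transect is not None:
            pops = sorted(pops, key=lambda p: transect[p])
        if region.ibd:
            p_prev = p_region
            for pop in pops:
                p_prev = _balding_nichols(rng, p_prev, region.fst_within)
                pop_freqs[pop] = p_prev
        else:
            for pop in pops:
                pop_freqs[pop] = _balding_nichols(rng, p_region,
                                                  region.fst_within)
    missing_regions = set(panel.table["region"]) - set(region_names)
    if missing_regions:
        raise ValueError(f"panel regions not in config: {missing_regions}")

    samples = panel.sample_ids
    dosage = np.empty((L, len(samples)), dtype=np.int8)
    for j, s in enumerate(samples):
        pop = panel.table.loc[panel.table["sample_id"] == s,
                              "population_id"].iloc[0]
        dosage[:, j] = rng.binomial(2, pop_freqs[pop])

    # replicate pairs: copy, then inject discordant singletons
    discordant_rows = []
    used: set[int] = set()
    col = {s: i for i, s in enumerate(samples)}
    for group, members in sorted(panel.replicate_groups().items()):
        first, second = members[0], members[1]
        dosage[:, col[second]] = dosage[:, col[first]]
        candidates = np.nonzero(dosage[:, col[first]] == 0)[0]
        candidates = np.array([c for c in candidates if c not in used])
        chosen = rng.choice(candidates, size=config.replicate_noise_snps,
                            replace=False)
        for c in chosen:
            dosage[c, col[second]] = 1
            used.add(int(c))
            discordant_rows.append((group, "snp_contig", int(c) + 1, int(c)))

    refs = _BASES[rng.integers(0, 4, size=L)]
    alts = np.array([_BASES[(list(_BASES).index(r) + 1 +
                             int(rng.integers(0, 3))) % 4] for r in refs])
    loci = pd.DataFrame({"chrom": "snp_contig",
                         "pos": np.arange(1, L + 1),
                         "ref": refs, "alt": alts})
    matrix = GenotypeMatrix(loci, list(samples), dosage)

    pops = list(pop_freqs)
    fst_true = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            pi, pj = pop_freqs[pops[i]], pop_freqs[pops[j]]
            hw = pi * (1 - pi) + pj * (1 - pj)
            hb = pi * (1 - pj) + pj * (1 - pi)
            fst_true[i, j] = fst_true[j, i] = 1 - hw.mean() / hb.mean()
    truth = {
        "pop_freqs": pd.DataFrame(pop_freqs),
        "pairwise_fst_true": PairwiseMatrix(tuple(pops), fst_true, kind="fst"),
        "replicate_discordant": pd.DataFrame(
            discordant_rows,
            columns=["replicate_group", "chrom", "pos", "locus_index"]),
    }
    return matrix, truth


# --------------------------------------------------------------- expression

def simulate_expression(config: SimulationConfig, panel: SamplePanel
                        ) -> tuple[ExpressionMatrix, dict]:
    """Log-normal TPM with planted modules, GED genes and DE genes.

    log2 TPM = baseline + population effect + module factor x loading +
    noise. Wild samples' noise s.d. is multiplied by ``ged_inflation_wild``
    on the flagged GED genes (these model loci whose expression is more
    variable in wild populations). The last ``rewired_module_count`` modules
    get an independent gene membership in the wild habitat (network rewiring).
    DE genes get a +/- ``de_log2fc`` shift in one designated weedy
    population each.
    """
    rng = _rng(config, 3)
    T = config.n_transcripts
    ids = [f"TR{i:06d}" for i in range(1, T + 1)]
    samples = panel.sample_ids
    habitats = panel.table.set_index("sample_id")["habitat"]
    pops_of = panel.table.set_index("sample_id")["population_id"]
    pops = panel.populations

    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=T)
    sigma = rng.uniform(*config.noise_log2_sd_range, size=T)

    # gene index bookkeeping: module blocks first, then rewired-wild pools,
    # then GED genes, then the DE pool
    sizes = rng.integers(config.module_size_range[0],
                         config.module_size_range[1] + 1,
                         size=config.n_modules)
    module_weedy = np.zeros(T, dtype=int)
    module_wild = np.zeros(T, dtype=int)
    cursor = 0
    for m, size in enumerate(sizes, start=1):
        module_weedy[cursor:cursor + size] = m
        module_wild[cursor:cursor + size] = m
        cursor += size
    n_rewired = min(config.rewired_module_count, config.n_modules)
    rewired = list(range(config.n_modules - n_rewired + 1,
                         config.n_modules + 1)) if n_rewired else []
    for m in rewired:
        size = int(sizes[m - 1])
        module_wild[module_wild == m] = 0
        module_wild[cursor:cursor + size] = m
        cursor += size
    de_pool_size = 4 * config.n_de_genes_per_pair
    needed = cursor + config.n_ged_genes + de_pool_size
    if needed > T:
        raise ValueError(
            f"n_transcripts={T} cannot hold the planted structure "
            f"(modules + GED + DE pools need {needed} genes)")
    ged_genes = np.arange(cursor, cursor + config.n_ged_genes)
    cursor += config.n_ged_genes
    de_truth: dict[str, dict[str, list[str]]] = {}
    weedy_pops = [p for p in pops if panel.habitat_of(p) == "weedy"]
    de_sign = {}
    de_pool = np.arange(cursor, cursor + de_pool_size)
    for pop in weedy_pops:
        if config.n_de_genes_per_pair == 0 or de_pool.size == 0:
            de_truth[pop] = {"up": [], "down": []}
            continue
        chosen = rng.choice(de_pool, size=min(config.n_de_genes_per_pair,
                                              de_pool.size), replace=False)
        signs = rng.choice([1, -1], size=chosen.size)
        de_sign[pop] = dict(zip(chosen.tolist(), signs.tolist()))
        de_truth[pop] = {
            "up": [ids[g] for g, s in de_sign[pop].items() if s > 0],
            "down": [ids[g] for g, s in de_sign[pop].items() if s < 0],
        }

    pop_eff = {p: rng.normal(0, config.pop_effect_sd, size=T) for p in pops}
    factors = rng.normal(0, 1.0, size=(config.n_modules + 1, len(samples)))

    x = np.empty((T, len(samples)))
    lam = config.module_loading
    for j, s in enumerate(samples):
        hab = habitats[s]
        pop = pops_of[s]
        membership = module_wild if hab == "wild" else module_weedy
        noise_sd = sigma.copy()
        if hab == "wild" and config.ged_inflation_wild != 1.0:
            noise_sd[ged_genes] *= config.ged_inflation_wild
        col = mu + pop_eff[pop] + rng.normal(0, 1.0, size=T) * noise_sd
        in_module = membership > 0
        col[in_module] += lam * factors[membership[in_module], j]
        if pop in de_sign:
            for g, sgn in de_sign[pop].items():
                col[g] += sgn * config.de_log2fc
        x[:, j] = col

    expr = ExpressionMatrix(pd.DataFrame(np.power(2.0, x), index=ids,
                                         columns=list(samples)))
    truth = {
        "ged_genes": [ids[g] for g in ged_genes],
        "de_genes": de_truth,
        "modules": pd.DataFrame({"transcript_id": ids,
                                 "module_weedy": module_weedy,
                                 "module_wild": module_wild}),
        "rewired_modules": rewired,
    }
    return expr, truth


# ---------------------------------------------------------------- sequences

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 1) non-stop codons + stop."""
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = _random_seq(rng, 3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _random_transcript(rng: np.random.Generator, n_codons: int,
                       utr: tuple[int, int] = (20, 60)) -> str:
    u5 = _random_seq(rng, int(rng.integers(*utr)))
    u3 = _random_seq(rng, int(rng.integers(*utr)))
    return u5 + _random_orf(rng, n_codons) + u3


def _mutate_synonymous(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Diverge a coding transcript, preferring silent changes.

    Mutations land in the UTRs or at third codon positions of the longest
    ORF, choosing a synonymous base when one exists — the purifying-selection
    regime expected of conserved homolog families. Nucleotide divergence is
    ``rate``; the protein stays nearly identical.
    """
    from Bio.Seq import Seq as _Seq

    orf = longest_orf(seq)
    if orf is None or orf.strand != "+":
        return _mutate(rng, seq, rate)
    # third positions of codons 2..end (never the initiator ATG)
    third = set(range(orf.start + 5, orf.start + 3 * orf.aa_length, 3))
    orf_end = orf.start + 3 * (orf.aa_length + 1)
    utr = [i for i in range(len(seq)) if i < orf.start or i >= orf_end]
    allowed = sorted(third) + utr
    n = min(max(1, int(round(rate * len(seq)))), len(allowed))
    s = list(seq)
    for pi in rng.choice(len(allowed), size=n, replace=False):
        p = allowed[int(pi)]
        alts = [b for b in "ACGT" if b != s[p]]
        if p in third:
            cstart = p - 2
            codon = "".join(s[cstart:cstart + 3])
            aa = str(_Seq(codon).translate())
            syn = [b for b in alts
                   if str(_Seq(codon[:2] + b).translate()) == aa]
            if not syn:  # Met/Trp: keep the reading frame stop-free at least
                syn = [b for b in alts if codon[:2] + b not in _STOPS]
            s[p] = syn[int(rng.integers(len(syn)))]
            continue
        s[p] = alts[int(rng.integers(len(alts)))]
    return "".join(s)


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            min_aa: int = 100, max_tries: int = 30) -> str:
    """Point-mutate at the given rate, keeping a >= min_aa-codon ORF."""
    n = max(1, int(round(rate * len(seq))))
    for _ in range(max_tries):
        s = list(seq)
        for p in rng.choice(len(seq), size=n, replace=False):
            choices = [b for b in "ACGT" if b != s[p]]
            s[p] = choices[int(rng.integers(0, 3))]
        out = "".join(s)
        orf = longest_orf(out)
        if orf is not None and orf.aa_length >= min_aa:
            return out
    return seq  # pathological case: return the unmutated original


ALS_GENE = "TR_ALS"
ALS_ORF_CODONS = 620
ALS_UTR5 = 24


def _als_transcript(rng: np.random.Generator) -> tuple[str, int]:
    """ALS-like transcript: >= 600-codon ORF with Pro (CCT) at codon 197 and
    Trp (TGG) at codon 574. Returns (sequence, 0-based ORF start)."""
    codons = ["ATG"]
    while len(codons) < ALS_ORF_CODONS:
        c = _random_seq(rng, 3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    codons[196] = "CCT"   # codon 197
    codons[573] = "TGG"   # codon 574
    codons.append("TAA")
    u5 = _random_seq(rng, ALS_UTR5)
    u3 = _random_seq(rng, 30)
    return u5 + "".join(codons) + u3, ALS_UTR5


def als_snp_table(orf_start: int) -> pd.DataFrame:
    """Transcript coordinates (1-based) of the planted resistance SNPs."""
    def pos(codon: int, codon_pos: int) -> int:
        return orf_start + (codon - 1) * 3 + codon_pos

    rows = [
        ("ALS_P197c1", ALS_GENE, pos(197, 1), "C", "T", 197, 1,
         "Pro197: CCT->TCT (Ser) alone; TTT (Phe) with P197c2"),
        ("ALS_P197c2", ALS_GENE, pos(197, 2), "C", "T", 197, 2,
         "Pro197: CCT->CTT (Leu) alone"),
        ("ALS_W574c2", ALS_GENE, pos(574, 2), "G", "T", 574, 2,
         "Trp574: TGG->TTG (Leu)"),
    ]
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt",
                                       "codon", "codon_pos", "note"])


def default_catalog() -> ResistanceCatalog:
    """Known ALS target-site resistance substitutions."""
    return ResistanceCatalog(pd.DataFrame(
        [("ALS", 197, "P", "S,L,F"), ("ALS", 574, "W", "L")],
        columns=["gene", "codon", "wildtype_aa", "resistant_aas"]))


def simulate_transcripts(config: SimulationConfig, panel: SamplePanel
                         ) -> tuple[TranscriptCollection,
                                    dict[str, TranscriptCollection], dict]:
    """Reference transcriptome, per-population collections and sequence truth.

    Each population's collection is the reference plus planted novel
    transcripts (absent from the reference and its paired population) and,
    for weedy populations, region-wide homolog families at 2-5 % divergence.
    The reference carries the ALS-like transcript.
    """
    rng = _rng(config, 4)
    ref_entries: dict[str, str] = {}
    for i in range(1, config.n_reference_transcripts + 1):
        ref_entries[f"TR{i:06d}"] = _random_transcript(
            rng, int(rng.integers(110, 160)))
    als_seq, als_orf_start = _als_transcript(rng)
    ref_entries[ALS_GENE] = als_seq
    reference = TranscriptCollection(ref_entries, label="reference")

    pairs = adjacent_pairs(panel)
    pair_of: dict[str, str] = {}
    for row in pairs.itertuples(index=False):
        pair_of[row.weedy_pop] = row.wild_pop
        pair_of.setdefault(row.wild_pop, row.weedy_pop)

    # region-wide weedy homolog families
    family_members: dict[str, dict[str, str]] = {}  # pop -> {name: seq}
    family_truth_rows = []
    regions = sorted({panel.region_of(p) for p in panel.populations})
    for region in regions:
        weedy_pops = [p for p in panel.populations
                      if panel.region_of(p) == region
                      and panel.habitat_of(p) == "weedy"]
        for fam in range(config.n_shared_weedy_unique):
            base = _random_transcript(rng, int(rng.integers(110, 140)))
            for pop in weedy_pops:
                rate = rng.uniform(*config.family_divergence_range)
                name = f"{region}_fam{fam + 1}_{pop}"
                family_members.setdefault(pop, {})[name] = _mutate_synonymous(
                    rng, base, rate)
                family_truth_rows.append((region, f"{region}_fam{fam + 1}",
                                          pop, name))

    collections: dict[str, TranscriptCollection] = {}
    unique_truth_rows = []
    for pop in panel.populations:
        entries = dict(ref_entries)
        for i in range(1, config.n_unique_transcripts_per_pop + 1):
            name = f"{pop}_uniq{i}"
            entries[name] = _random_transcript(rng, int(rng.integers(110, 150)))
            unique_truth_rows.append((pop, name))
        for name, seq in family_members.get(pop, {}).items():
            entries[name] = seq
            unique_truth_rows.append((pop, name))
        collections[pop] = TranscriptCollection(entries, label=pop)

    truth = {
        "unique_transcripts": pd.DataFrame(
            unique_truth_rows, columns=["population_id", "transcript_id"]),
        "weedy_families": pd.DataFrame(
            family_truth_rows,
            columns=["region", "family_id", "population_id", "transcript_id"]),
        "als_orf_start": als_orf_start,
        "als_snps": als_snp_table(als_orf_start),
        "pairs": pairs,
    }
    return reference, collections, truth


# ------------------------------------------------------------------- bundle

@dataclass
class SyntheticBundle:
    config: SimulationConfig
    panel: SamplePanel
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    reference: TranscriptCollection
    populations: dict[str, TranscriptCollection]
    annotation: "object"
    catalog: ResistanceCatalog
    queries: TranscriptCollection
    pairs: pd.DataFrame
    truth: dict


def _als_genotypes(config: SimulationConfig, panel: SamplePanel,
                   als_snps: pd.DataFrame, als_seq: str,
                   rng: np.random.Generator
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Genotypes on the ALS transcript: planted resistance carriers in both
    habitats plus neutral SNPs, two of which differ strongly in frequency
    between habitats."""
    samples = panel.sample_ids
    habitats = panel.table.set_index("sample_id")["habitat"]
    rows = []
    dosages = []
    for snp in als_snps.itertuples(index=False):
        d = np.zeros(len(samples), dtype=np.int8)
        for j, s in enumerate(samples):
            frac = config.als_resistance_carrier_fraction[habitats[s]]
            if rng.uniform() < frac:
                d[j] = 2 if rng.uniform() < 0.1 else 1
        rows.append((snp.chrom, snp.pos, snp.ref, snp.alt))
        dosages.append(d)
    orf_start = ALS_UTR5
    taken = set(als_snps["pos"])
    neutral_pos = []
    pos = orf_start + 9  # inside the ORF, away from codon 1
    while len(neutral_pos) < config.n_neutral_als_snps:
        if pos not in taken:
            neutral_pos.append(pos)
        pos += 97
    for i, p in enumerate(neutral_pos):
        if i < 2:  # strongly differentiated between habitats
            freq = {"weedy": 0.6, "wild": 0.05}
        else:
            f = rng.uniform(0.1, 0.4)
            freq = {"weedy": f, "wild": f}
        d = np.array([rng.binomial(2, freq[habitats[s]]) for s in samples],
                     dtype=np.int8)
        ref = als_seq[p - 1]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        rows.append((ALS_GENE, int(p), ref, alt))
        dosages.append(d)
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    order = np.argsort(loci["pos"].to_numpy(), kind="stable")
    return (loci.iloc[order].reset_index(drop=True),
            np.vstack(dosages)[order])


def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate the full input bundle plus truth tables."""
    from .datatypes import AnnotationMap  # local to avoid clutter above

    panel = simulate_panel(config)
    genotypes, gt_truth = simulate_genotypes(config, panel)
    expression, expr_truth = simulate_expression(config, panel)
    reference, collections, seq_truth = simulate_transcripts(config, panel)

    rng = _rng(config, 5)
    als_loci, als_dosage = _als_genotypes(config, panel,
                                          seq_truth["als_snps"],
                                          reference[ALS_GENE], rng)
    # replicate members are RNA from one plant: copy genotypes at ALS loci
    col = {s: i for i, s in enumerate(panel.sample_ids)}
    for _, members in sorted(panel.replicate_groups().items()):
        als_dosage[:, col[members[1]]] = als_dosage[:, col[members[0]]]
    loci = pd.concat([genotypes.loci, als_loci], ignore_index=True)
    dosage = np.vstack([genotypes.dosage, als_dosage])
    genotypes = GenotypeMatrix(loci, genotypes.samples, dosage)

    # ALS expression row: mildly higher in weedy samples (pseudo-amplification)
    habitats = panel.table.set_index("sample_id")["habitat"]
    shift = np.array([1.0 if habitats[s] == "weedy" else 0.0
                      for s in panel.sample_ids])
    als_expr = np.power(2.0, 5.0 + shift + rng.normal(0, 0.4,
                                                      len(panel.sample_ids)))
    values = expression.values.copy()
    values.loc[ALS_GENE] = als_expr
    expression = ExpressionMatrix(values)

    # annotation: expression transcripts and planted uniques / families
    terms = [f"GO:{i:07d}" for i in range(1, config.n_terms + 1)]
    descriptions = {t: f"function_{i + 1}" for i, t in enumerate(terms)}
    ann_terms: dict[str, set[str]] = {}
    for tid in expression.values.index:
        k = int(rng.poisson(1.2))
        if k:
            ann_terms[tid] = set(rng.choice(terms, size=min(k, len(terms)),
                                            replace=False))
    fam_term = {}
    for fam_id in sorted(set(seq_truth["weedy_families"]["family_id"])):
        fam_term[fam_id] = terms[int(rng.integers(0, len(terms)))]
    for row in seq_truth["weedy_families"].itertuples(index=False):
        ann_terms.setdefault(row.transcript_id, set()).add(fam_term[row.family_id])
    for row in seq_truth["unique_transcripts"].itertuples(index=False):
        if row.transcript_id not in ann_terms:
            ann_terms[row.transcript_id] = {
                terms[int(rng.integers(0, len(terms)))]}
    annotation = AnnotationMap(ann_terms, descriptions)

    # herbicide query: the ALS sequence at ~2 % divergence (still >= 90/90)
    query_seq = _mutate(rng, reference[ALS_GENE], 0.02, min_aa=400)
    queries = TranscriptCollection({"ALS_query": query_seq}, label="queries")

    truth = {**gt_truth, **expr_truth, **seq_truth}
    return SyntheticBundle(config, panel, genotypes, expression, reference,
                           collections, annotation, default_catalog(),
                           queries, seq_truth["pairs"], truth)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "transcripts").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    paths["panel"] = out / "panel.tsv"
    aio.write_panel(bundle.panel, paths["panel"])
    paths["vcf"] = out / "genotypes.vcf"
    aio.write_vcf(bundle.genotypes, paths["vcf"])
    paths["expression"] = out / "expression.tsv"
    aio.write_expression(bundle.expression, paths["expression"])
    paths["reference"] = out / "reference.fasta"
    aio.write_fasta(bundle.reference, paths["reference"])
    for pop, coll in bundle.populations.items():
        p = out / "transcripts" / f"{pop}.fasta"
        aio.write_fasta(coll, p)
        paths[f"transcripts/{pop}"] = p
    paths["annotation"] = out / "annotation.tsv"
    aio.write_annotation(bundle.annotation, paths["annotation"])
    paths["catalog"] = out / "resistance_catalog.tsv"
    aio.write_catalog(bundle.catalog, paths["catalog"])
    paths["queries"] = out / "herbicide_queries.fasta"
    aio.write_fasta(bundle.queries, paths["queries"])
    paths["pairs"] = out / "pairs.tsv"
    bundle.pairs.to_csv(paths["pairs"], sep="\t", index=False)

    for key in ("replicate_discordant", "unique_transcripts",
                "weedy_families", "als_snps", "modules"):
        p = out / "truth" / f"{key}.tsv"
        bundle.truth[key].to_csv(p, sep="\t", index=False)
        paths[f"truth/{key}"] = p
    (out / "truth" / "ged_genes.tsv").write_text(
        "\n".join(bundle.truth["ged_genes"]) + "\n")
    paths["truth/ged_genes"] = out / "truth" / "ged_genes.tsv"
    return paths
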