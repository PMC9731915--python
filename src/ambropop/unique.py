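"""Population-unique transcript workflow at the sequence level.

A transcript is "unique" to a population when it has no counterpart (above a
k-mer containment threshold) in the reference transcriptome or in the paired
population from the other habitat. Survivors are filtered for coding
potential (longest ORF), grouped into cross-population homolog families by
protein k-mer similarity, and intersected on functional annotation terms.

Read mapping and de novo assembly are replaced by transcript-level canonical
k-mer containment, which preserves the workflow's presence/absence set logic
at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
from Bio.Seq import Seq

from .datatypes import AnnotationMap, SamplePanel, TranscriptCollection

DEFAULT_K_NT = 21
DEFAULT_K_AA = 6
DEFAULT_MAP_THRESHOLD = 0.8
DEFAULT_SIM_THRESHOLD = 0.5
DEFAULT_MIN_AA = 100

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical_kmers(seq: str, k: int = DEFAULT_K_NT) -> set[str]:
    """Distinct strand-normalized k-mers (lexicographic min of k-mer and its
    reverse complement); k-mers containing N are skipped."""
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if "N" in km:
            continue
        rc = revcomp(km)
        out.add(km if km <= rc else rc)
    return out


def collection_kmers(target: TranscriptCollection, k: int = DEFAULT_K_NT) -> set[str]:
    """Union of canonical k-mers over every sequence in a collection."""
    out: set[str] = set()
    for seq in target.entries.values():
        if len(seq) >= k:
            out |= canonical_kmers(seq, k)
    return out


def containment(query: str, target: TranscriptCollection | set[str],
                k: int = DEFAULT_K_NT) -> float:
    """Fraction of the query's distinct canonical k-mers found in the target."""
    qk = canonical_kmers(query, k)
    if not qk:
        return 0.0
    tk = target if isinstance(target, set) else collection_kmers(target, k)
    return len(qk & tk) / len(qk)


# ------------------------------------------------------------------ uniques

def extract_unique(pop_transcripts: TranscriptCollection,
                   reference: TranscriptCollection,
                   paired_pop_transcripts: TranscriptCollection,
                   map_threshold: float = DEFAULT_MAP_THRESHOLD,
                   k: int = DEFAULT_K_NT) -> TranscriptCollection:
    """Transcripts of a population absent from the reference and its pair.

    Stage 1 drops transcripts with containment >= map_threshold against the
    reference (the "mapped" fraction); stage 2 drops survivors with
    containment >= map_threshold against the paired population. Raising the
    threshold can only enlarge the unique set (anti-monotone filter).
    """
    if not 0 < map_threshold <= 1:
        raise ValueError("map_threshold must be in (0, 1]")
    ref_k = collection_kmers(reference, k)
    pair_k = collection_kmers(paired_pop_transcripts, k)
    keep: dict[str, str] = {}
    for name, seq in pop_transcripts.entries.items():
        if len(seq) < k:
            continue
        if containment(seq, ref_k, k) >= map_threshold:
            continue
        if containment(seq, pair_k, k) >= map_threshold:
            continue
        keep[name] = seq
    return TranscriptCollection(keep, label=f"{pop_transcripts.label}_unique")


# --------------------------------------------------------------------- ORFs

class Orf(NamedTuple):
    strand: str        # "+" or "-"
    start: int         # 0-based start of ATG on the given strand's sequence
    aa_length: int     # codons before the stop
    protein: str


def longest_orf(seq: str) -> Orf | None:
    """Longest ATG-initiated, stop-terminated ORF over both strands, 3 frames."""
    best: Orf | None = None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            i = frame
            codons = [s[j:j + 3] for j in range(frame, len(s) - 2, 3)]
            start_idx = None
            for ci, codon in enumerate(codons):
                if codon in ("TAA", "TAG", "TGA"):
                    if start_idx is not None:
                        aa_len = ci - start_idx
                        if best is None or aa_len > best.aa_length:
                            nt = s[frame + 3 * start_idx: frame + 3 * ci]
                            best = Orf(strand, frame + 3 * start_idx, aa_len,
                                       str(Seq(nt).translate()))
                        start_idx = None
                elif start_idx is None and codon == "ATG":
                    start_idx = ci
    return best


def orf_filter(collection: TranscriptCollection, min_aa: int = DEFAULT_MIN_AA
               ) -> tuple[TranscriptCollection, dict[str, Orf]]:
    """Keep transcripts whose longest ORF is >= min_aa codons.

    Returns the filtered collection and the retained ORFs (for downstream
    codon mapping). Idempotent: re-filtering the output changes nothing.
    """
    keep: dict[str, str] = {}
    orfs: dict[str, Orf] = {}
    for name, seq in collection.entries.items():
        orf = longest_orf(seq)
        if orf is not None and orf.aa_length >= min_aa:
            keep[name] = seq
            orfs[name] = orf
    return TranscriptCollection(keep, label=collection.label), orfs


# ---------------------------------------------------------------- homologs

@dataclass
class HomologGroup:
    group_id: int
    members: list[tuple[str, str]]  # (population, transcript id)
    representative: str             # transcript id of an arbitrary member

    @property
    def populations(self) -> set[str]:
        return {p for p, _ in self.members}

    @property
    def is_singleton(self) -> bool:
        return len(self.members) < 2 or len(self.populations) < 2


def _protein_kmers(protein: str, k: int = DEFAULT_K_AA) -> set[str]:
    return {protein[i:i + k] for i in range(len(protein) - k + 1)}


def homolog_grouping(collections: Mapping[str, TranscriptCollection],
                     sim_threshold: float = DEFAULT_SIM_THRESHOLD,
                     min_aa: int = DEFAULT_MIN_AA,
                     k_aa: int = DEFAULT_K_AA) -> list[HomologGroup]:
    """Cluster per-population unique transcripts into homolog families.

    Pairwise similarity is the max directional containment of translated-ORF
    protein k-mers; edges at >= sim_threshold; families are connected
    components of the resulting graph. Transcripts without a qualifying ORF
    are skipped.
    """
    if len(collections) < 2:
        raise ValueError("homolog grouping needs >= 2 populations")
    nodes: list[tuple[str, str]] = []
    kmers: list[set[str]] = []
    for pop, coll in collections.items():
        _, orfs = orf_filter(coll, min_aa=min_aa)
        for name, orf in orfs.items():
            pk = _protein_kmers(orf.protein, k_aa)
            if pk:
                nodes.append((pop, name))
                kmers.append(pk)
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            inter = len(kmers[i] & kmers[j])
            if not inter:
                continue
            sim = inter / min(len(kmers[i]), len(kmers[j]))
            if sim >= sim_threshold:
                g.add_edge(i, j)
    groups = []
    for gid, comp in enumerate(sorted(nx.connected_components(g),
                                      key=lambda c: (-len(c), min(c)))):
        members = sorted(nodes[i] for i in comp)
        groups.append(HomologGroup(gid, members, members[0][1]))
    return groups


def shared_by_all(groups: Iterable[HomologGroup],
                  populations: Iterable[str]) -> list[HomologGroup]:
    """Groups with at least one member from every listed population."""
    pops = set(populations)
    return [g for g in groups if pops <= g.populations]


# ------------------------------------------------------- functional overlap

@dataclass
class FunctionalOverlap:
    terms_per_region: dict[str, set[str]]      # region -> term ids (one habitat)
    shared_across_regions: set[str] = field(default_factory=set)
    specific_terms: set[str] = field(default_factory=set)


def group_terms(groups: Iterable[HomologGroup],
                annotation: AnnotationMap) -> set[str]:
    """Union of member annotations over a set of homolog groups."""
    out: set[str] = set()
    for g in groups:
        for _, transcript in g.members:
            out |= annotation.of(transcript)
    return out


def functional_overlap(shared_groups_by_region: Mapping[str, Iterable[HomologGroup]],
                       annotation: AnnotationMap,
                       other_habitat_terms: set[str] | None = None
                       ) -> FunctionalOverlap:
    """Term sets of region-shared homolog groups, their cross-region
    intersection, and the habitat-specific remainder after subtracting the
    other habitat's terms."""
    per_region = {region: group_terms(groups, annotation)
                  for region, groups in shared_groups_by_region.items()}
    shared = set.intersection(*per_region.values()) if per_region else set()
    specific = shared - (other_habitat_terms or set())
    return FunctionalOverlap(per_region, shared, specific)
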