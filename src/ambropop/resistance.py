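"""Herbicide target-gene analysis.

Locates target genes in a transcriptome by local alignment (90 % identity /
90 % coverage filter), compares their expression between habitats, tests
per-SNP allele-frequency differences with two-sided Fisher exact tests, and
annotates codon-level amino-acid changes against a catalog of known
target-site resistance substitutions (e.g. ALS Pro-197 and Trp-574).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from scipy import stats

from .datatypes import (MISSING, ExpressionMatrix, GenotypeMatrix,
                        ResistanceCatalog, SamplePanel, TranscriptCollection)
from .unique import canonical_kmers, revcomp

# amino-acid property groups for conservative/nonconservative calls
PROPERTY_GROUPS: dict[str, str] = {}
for _group, _aas in {
    "aliphatic": "AVLIM",
    "aromatic": "FWY",
    "polar": "STNQ",
    "positive": "KRH",
    "negative": "DE",
    "special": "CGP",
}.items():
    for _aa in _aas:
        PROPERTY_GROUPS[_aa] = _group


# ------------------------------------------------------------ gene finding

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _alignment_stats(alignment) -> tuple[float, int]:
    """(identity over aligned columns, aligned query length)."""
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    q_aligned = int(sum(e - s for s, e in alignment.aligned[1]))
    return identity, q_aligned


def find_target_genes(reference: TranscriptCollection,
                      queries: TranscriptCollection,
                      min_identity: float = 0.90,
                      min_coverage: float = 0.90,
                      prescreen_k: int = 21,
                      prescreen_containment: float = 0.05) -> pd.DataFrame:
    """Best local-alignment hits of each query gene in the reference.

    Scoring: match +1, mismatch -1, gap open -2, extend -1; both strands.
    A hit needs identity >= min_identity over the aligned region and an
    aligned query length >= min_coverage x query length. A cheap k-mer
    containment prescreen skips hopeless reference transcripts.

    Returns columns: query, reference, strand, identity, coverage, score.
    """
    aligner = _make_aligner()
    rows = []
    ref_kmers = {name: canonical_kmers(seq, prescreen_k)
                 for name, seq in reference.entries.items()
                 if len(seq) >= prescreen_k}
    for qname, qseq in queries.entries.items():
        qk = canonical_kmers(qseq, prescreen_k) if len(qseq) >= prescreen_k \
            else set()
        for rname, rseq in reference.entries.items():
            if qk and rname in ref_kmers:
                share = len(qk & ref_kmers[rname]) / len(qk)
                if share < prescreen_containment:
                    continue
            best = None
            for strand, q in (("+", qseq), ("-", revcomp(qseq))):
                alns = aligner.align(rseq, q)
                if not len(alns):
                    continue
                aln = alns[0]
                identity, q_aligned = _alignment_stats(aln)
                coverage = q_aligned / len(qseq)
                cand = (aln.score, strand, identity, coverage)
                if best is None or cand[0] > best[0]:
                    best = cand
            if best is None:
                continue
            score, strand, identity, coverage = best
            if identity >= min_identity and coverage >= min_coverage:
                rows.append((qname, rname, strand, identity, coverage, score))
    return pd.DataFrame(rows, columns=["query", "reference", "strand",
                                       "identity", "coverage", "score"])


# ------------------------------------------------------------- expression

def expression_compare(expr: ExpressionMatrix, panel: SamplePanel,
                       gene_transcripts: Mapping[str, Iterable[str]]
                       ) -> pd.DataFrame:
    """Per-gene habitat comparison of summed, log2(TPM+1) expression.

    Returns columns: gene, median_log2_weedy, median_log2_wild, p,
    expressed (False when the gene is unexpressed everywhere, with p = 1).
    """
    t = panel.table
    weedy = list(t.loc[t["habitat"] == "weedy", "sample_id"])
    wild = list(t.loc[t["habitat"] == "wild", "sample_id"])
    rows = []
    for gene, transcripts in gene_transcripts.items():
        tr = [x for x in transcripts if x in expr.values.index]
        if not tr:
            raise ValueError(f"gene {gene!r} has no matched transcript")
        total = expr.values.loc[tr].sum(axis=0)
        logv = np.log2(total + 1)
        x, y = logv[weedy].to_numpy(), logv[wild].to_numpy()
        expressed = bool((total > 0).any())
        if not expressed or (np.all(x == x[0]) and np.all(y == x[0])):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append((gene, float(np.median(x)), float(np.median(y)), p,
                     expressed))
    return pd.DataFrame(rows, columns=["gene", "median_log2_weedy",
                                       "median_log2_wild", "p", "expressed"])


# ------------------------------------------------------------ Fisher exact

@lru_cache(maxsize=None)
def _comb(n: int, k: int) -> int:
    return math.comb(n, k)


def fisher_exact_two_sided(table: tuple[tuple[int, int], tuple[int, int]]
                           ) -> float:
    """Two-sided Fisher exact p by exact integer arithmetic.

    Sums hypergeometric probabilities of all tables (same margins) whose
    probability is <= the observed table's, comparing exact integer
    numerators so ties are decided without floating-point ambiguity.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    if n == 0 or row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
        return 1.0
    lo, hi = max(0, col1 - row2), min(col1, row1)
    # numerators share the denominator C(n, col1)
    obs = _comb(row1, a) * _comb(row2, col1 - a)
    num = sum(_comb(row1, k) * _comb(row2, col1 - k)
              for k in range(lo, hi + 1) if
              _comb(row1, k) * _comb(row2, col1 - k) <= obs)
    return min(1.0, num / _comb(n, col1))


def snp_allele_freq_test(matrix: GenotypeMatrix, panel: SamplePanel,
                         gene_region: str | None = None,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-SNP weedy/wild allele-frequency comparison (two-sided Fisher).

    ``gene_region`` restricts to loci on one chrom/transcript. Each genotyped
    sample contributes two alleles; missing genotypes are excluded.

    Returns columns: chrom, pos, ref, alt, freq_weedy, freq_wild, p,
    significant.
    """
    m = matrix
    if gene_region is not None:
        m = m.subset_loci((m.loci["chrom"] == gene_region).to_numpy())
    t = panel.table
    idx_w = m.sample_index([s for s in t.loc[t["habitat"] == "weedy",
                                             "sample_id"] if s in m.samples])
    idx_x = m.sample_index([s for s in t.loc[t["habitat"] == "wild",
                                             "sample_id"] if s in m.samples])
    rows = []
    for i in range(m.n_loci):
        row = m.loci.iloc[i]
        out = []
        for idx in (idx_w, idx_x):
            d = m.dosage[i, idx]
            gen = d != MISSING
            alt = int(d[gen].sum())
            tot = int(2 * gen.sum())
            out.append((alt, tot - alt, alt / tot if tot else np.nan))
        (aw, rw, fw), (ax_, rx, fx) = out
        p = fisher_exact_two_sided(((aw, rw), (ax_, rx)))
        rows.append((row["chrom"], int(row["pos"]), row["ref"], row["alt"],
                     fw, fx, p, p <= alpha))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "freq_weedy", "freq_wild", "p",
                                       "significant"])


# ------------------------------------------------------- codon annotation

@dataclass(frozen=True)
class CodonChange:
    positions: tuple[int, ...]   # transcript positions (1-based) of the SNPs
    codon_number: int            # 1-based within the ORF
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    classification: str          # synonymous | conservative | nonconservative
    known_resistance: bool


def classify_substitution(ref_aa: str, alt_aa: str) -> str:
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*" or ref_aa == "*":
        return "nonconservative"
    same_group = PROPERTY_GROUPS.get(ref_aa) == PROPERTY_GROUPS.get(alt_aa)
    return "conservative" if same_group else "nonconservative"


def annotate_codon_changes(sequence: str, orf_start: int, orf_length_nt: int,
                           snps: pd.DataFrame, catalog: ResistanceCatalog,
                           gene: str = "ALS",
                           codon_offset: int = 0) -> list[CodonChange]:
    """Map SNPs to codons, translate, and flag known resistance substitutions.

    ``orf_start`` is the 0-based transcript offset of the ORF's first base;
    ``snps`` needs columns pos (1-based transcript), ref, alt. SNPs falling
    in the same codon are applied jointly (e.g. the Pro-197-Phe double
    mutation). ``codon_offset`` is added to the ORF codon number to express
    standardized (Arabidopsis-aligned) numbering when it differs; catalog
    lookups use the standardized number.

    SNPs outside the ORF are reported as a CodonChange with codon_number 0
    and classification "non_coding".
    """
    changes: list[CodonChange] = []
    by_codon: dict[int, list[tuple[int, str, str]]] = {}
    for snp in snps.itertuples(index=False):
        pos0 = int(snp.pos) - 1
        if not (orf_start <= pos0 < orf_start + orf_length_nt):
            changes.append(CodonChange((int(snp.pos),), 0, "", "", "", "",
                                       "non_coding", False))
            continue
        in_orf = pos0 - orf_start
        codon_num = in_orf // 3 + 1
        if str(sequence[pos0]).upper() != str(snp.ref).upper():
            raise ValueError(
                f"SNP ref {snp.ref!r} does not match transcript at pos {snp.pos}")
        by_codon.setdefault(codon_num, []).append(
            (int(snp.pos), str(snp.ref).upper(), str(snp.alt).upper()))
    for codon_num, muts in sorted(by_codon.items()):
        cstart = orf_start + (codon_num - 1) * 3
        ref_codon = sequence[cstart:cstart + 3].upper()
        alt = list(ref_codon)
        for pos, _ref, alt_base in muts:
            alt[(pos - 1) - cstart] = alt_base
        alt_codon = "".join(alt)
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        std_codon = codon_num + codon_offset
        known = alt_aa in catalog.resistant_aas(gene, std_codon) \
            and ref_aa != alt_aa
        changes.append(CodonChange(tuple(p for p, _, _ in muts), std_codon,
                                   ref_codon, alt_codon, ref_aa, alt_aa,
                                   classify_substitution(ref_aa, alt_aa),
                                   known))
    return changes


# ---------------------------------------------------------------- tallies

def genotype_tally(matrix: GenotypeMatrix, panel: SamplePanel,
                   positions: Iterable[tuple[str, int]]) -> pd.DataFrame:
    """Genotype counts (0/0, 0/1, 1/1, missing) per habitat at given loci,
    plus the within-habitat resistant(alt)-allele carrier frequency."""
    t = panel.table
    habitat_samples = {h: [s for s in t.loc[t["habitat"] == h, "sample_id"]
                           if s in matrix.samples]
                       for h in ("weedy", "wild")}
    key = {(c, int(p)): i for i, (c, p) in
           enumerate(zip(matrix.loci["chrom"], matrix.loci["pos"]))}
    rows = []
    for chrom, pos in positions:
        if (chrom, int(pos)) not in key:
            raise KeyError(f"position {chrom}:{pos} not in matrix")
        i = key[(chrom, int(pos))]
        for habitat, samples in habitat_samples.items():
            d = matrix.dosage[i, matrix.sample_index(samples)]
            n00 = int((d == 0).sum())
            n01 = int((d == 1).sum())
            n11 = int((d == 2).sum())
            nmiss = int((d == MISSING).sum())
            ngen = n00 + n01 + n11
            carrier = (n01 + n11) / ngen if ngen else np.nan
            alt_freq = (n01 + 2 * n11) / (2 * ngen) if ngen else np.nan
            rows.append((chrom, int(pos), habitat, n00, n01, n11, nmiss,
                         carrier, alt_freq))
    return pd.DataFrame(rows, columns=["chrom", "pos", "habitat", "n_00",
                                       "n_01", "n_11", "n_missing",
                                       "carrier_freq", "alt_allele_freq"])
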