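"""Population-genetic statistics on transcriptome SNPs.

Covers the variant-level quality filter (replicate concordance), per-population
diversity (pi, Ho, He), Weir-Cockerham (1984) pairwise FST, great-circle
distances, Mantel tests for isolation by distance, identity-by-state PCoA and
a neighbor-joining sample tree.
"""

from __future__ import annotations

import io as _io
import logging
import math
from itertools import permutations

import numpy as np
import pandas as pd
import skbio

from .datatypes import MISSING, GenotypeMatrix, PairwiseMatrix, SamplePanel

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given data (e.g. no usable loci)."""


# ---------------------------------------------------------- variant filter

def replicate_concordance_filter(
    matrix: GenotypeMatrix, panel: SamplePanel
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep loci whose variant status agrees within every replicate pair.

    Biological replicates are RNA from the same plant, so a real SNP must be
    called in both; a locus is removed when, within any replicate group, one
    genotyped member carries the alternate allele and another does not.
    Groups with fewer than two genotyped members at a locus impose no
    constraint there; groups with < 2 members present in the matrix are
    ignored with a warning.

    Returns the filtered matrix and a report of removed loci
    (columns: chrom, pos, replicate_group).
    """
    keep = np.ones(matrix.n_loci, dtype=bool)
    removed_by: dict[int, str] = {}
    for group, members in panel.replicate_groups().items():
        present = [m for m in members if m in matrix.samples]
        if len(present) < 2:
            log.warning("replicate group %s has < 2 members in matrix; ignored",
                        group)
            continue
        d = matrix.dosage[:, matrix.sample_index(present)]
        genotyped = d != MISSING
        carrier = (d > 0) & genotyped
        n_gen = genotyped.sum(axis=1)
        n_car = carrier.sum(axis=1)
        # discordant: some but not all genotyped members carry the alt allele
        discordant = (n_gen >= 2) & (n_car > 0) & (n_car < n_gen)
        for i in np.nonzero(discordant)[0]:
            removed_by.setdefault(int(i), group)
        keep &= ~discordant
    report = pd.DataFrame(
        [(matrix.loci.iloc[i]["chrom"], matrix.loci.iloc[i]["pos"], g)
         for i, g in sorted(removed_by.items())],
        columns=["chrom", "pos", "replicate_group"],
    )
    return matrix.subset_loci(keep), report


# ------------------------------------------------------------- diversity

def _pop_dosage(matrix: GenotypeMatrix, panel: SamplePanel,
                population: str) -> np.ndarray:
    samples = [s for s in panel.samples_of(population) if s in matrix.samples]
    if len(samples) < 2:
        raise UndefinedStatisticError(
            f"population {population!r} has < 2 genotyped samples")
    return matrix.dosage[:, matrix.sample_index(samples)]


def nucleotide_diversity(matrix: GenotypeMatrix, panel: SamplePanel,
                         population: str) -> float:
    """Per-site nucleotide diversity, averaged over loci.

    pi_site = (# pairwise allele differences) / C(2n, 2) from allele counts;
    loci with fewer than two genotyped samples are skipped.
    """
    d = _pop_dosage(matrix, panel, population)
    genotyped = d != MISSING
    n_gen = genotyped.sum(axis=1)
    usable = n_gen >= 2
    if not usable.any():
        raise UndefinedStatisticError("no locus with >= 2 genotyped samples")
    n_alleles = 2 * n_gen[usable]
    n_alt = np.where(genotyped, d, 0).sum(axis=1)[usable]
    pairs = n_alleles * (n_alleles - 1) / 2
    pi_site = n_alt * (n_alleles - n_alt) / pairs
    return float(pi_site.mean())


def heterozygosity(matrix: GenotypeMatrix, panel: SamplePanel,
                   population: str) -> tuple[float, float]:
    """(Ho, He): observed heterozygote fraction and 2p(1-p), averaged over loci."""
    d = _pop_dosage(matrix, panel, population)
    genotyped = d != MISSING
    n_gen = genotyped.sum(axis=1)
    usable = n_gen >= 2
    if not usable.any():
        raise UndefinedStatisticError("no locus with >= 2 genotyped samples")
    het = ((d == 1) & genotyped).sum(axis=1)[usable]
    ho = float((het / n_gen[usable]).mean())
    p = np.where(genotyped, d, 0).sum(axis=1)[usable] / (2 * n_gen[usable])
    he = float((2 * p * (1 - p)).mean())
    return ho, he


def diversity_table(matrix: GenotypeMatrix, panel: SamplePanel) -> pd.DataFrame:
    """Per-population pi, Ho, He (populations with < 2 samples skipped)."""
    rows = []
    for pop in panel.populations:
        try:
            pi = nucleotide_diversity(matrix, panel, pop)
            ho, he = heterozygosity(matrix, panel, pop)
        except UndefinedStatisticError as e:
            log.warning("diversity_table: skipping %s (%s)", pop, e)
            continue
        rows.append((pop, panel.habitat_of(pop), panel.region_of(pop),
                     len(panel.samples_of(pop)), pi, ho, he))
    return pd.DataFrame(rows, columns=["population_id", "habitat", "region",
                                       "n_samples", "pi", "Ho", "He"])


# ------------------------------------------------------------------- FST

def _wc84_components(d1: np.ndarray, d2: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-locus variance components a, b, c for 2 pops.

    d1, d2: loci x samples dosage arrays (missing allowed). Loci where either
    population has no genotyped sample, or nbar <= 1, or nc <= 0, yield NaN.
    """
    r = 2
    comps = []
    ns, ps, hs = [], [], []
    for d in (d1, d2):
        gen = d != MISSING
        n = gen.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(gen, d, 0).sum(axis=1) / (2 * n)
            h = ((d == 1) & gen).sum(axis=1) / n
        ns.append(n)
        ps.append(p)
        hs.append(h)
    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = hs
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    bad = (n1 == 0) | (n2 == 0) | (nbar <= 1) | ~(nc > 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_fst(matrix: GenotypeMatrix, panel: SamplePanel,
           pop1: str, pop2: str) -> float:
    """Multi-locus Weir-Cockerham FST between two populations (ratio of sums).

    Negative per-locus components are retained in the sums (standard
    estimator behaviour); loci with undefined components are skipped.
    """
    d1 = _pop_dosage(matrix, panel, pop1)
    d2 = _pop_dosage(matrix, panel, pop2)
    a, b, c = _wc84_components(d1, d2)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[ok].sum()
    if not ok.any() or denom == 0:
        raise UndefinedStatisticError(
            f"FST undefined for {pop1}/{pop2}: no informative loci")
    return float(a[ok].sum() / denom)


def pairwise_fst(matrix: GenotypeMatrix, panel: SamplePanel) -> PairwiseMatrix:
    """Pairwise WC84 FST over all populations with >= 2 genotyped samples."""
    pops = []
    for pop in panel.populations:
        n = len([s for s in panel.samples_of(pop) if s in matrix.samples])
        if n >= 2:
            pops.append(pop)
        else:
            log.warning("pairwise_fst: excluding %s (< 2 samples)", pop)
    m = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            m[i, j] = m[j, i] = wc_fst(matrix, panel, pops[i], pops[j])
    return PairwiseMatrix(tuple(pops), m, kind="fst")


# -------------------------------------------------------------- geography

def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (Earth radius 6371 km)."""
    la1, lo1, la2, lo2 = map(math.radians, (lat1, lon1, lat2, lon2))
    h = (math.sin((la2 - la1) / 2) ** 2
         + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geographic_distance(panel: SamplePanel) -> PairwiseMatrix:
    """Great-circle distances (km) between population coordinate centroids."""
    cent = panel.table.groupby("population_id", sort=False)[
        ["latitude", "longitude"]].mean()
    if cent.isna().any().any():
        bad = cent.index[cent.isna().any(axis=1)][0]
        raise ValueError(f"missing coordinates for population {bad!r}")
    pops = list(cent.index)
    m = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            m[i, j] = m[j, i] = haversine_km(
                cent.iloc[i, 0], cent.iloc[i, 1], cent.iloc[j, 0], cent.iloc[j, 1])
    return PairwiseMatrix(tuple(pops), m, kind="km")


# ------------------------------------------------------------------ Mantel

def mantel_test(m1: PairwiseMatrix, m2: PairwiseMatrix, n_perm: int = 999,
                seed: int = 0, exact: bool = False) -> tuple[float, float]:
    """One-sided Mantel test for positive matrix association.

    r is the Pearson correlation of the lower triangles; the null permutes
    rows+columns of ``m2`` jointly. With ``exact=True`` all n! permutations
    are enumerated (identity included) and p = #(r* >= r)/n!; otherwise
    p = (1 + #(r* >= r)) / (1 + n_perm) over seeded random permutations.
    """
    if m1.labels != m2.labels:
        raise ValueError("matrices must share labels and order")
    n = len(m1.labels)
    if n < 4:
        raise ValueError("Mantel test needs >= 4 labels")
    x = m1.condensed()
    if x.std() == 0:
        raise UndefinedStatisticError("zero variance in first matrix triangle")
    if m2.condensed().std() == 0:
        raise UndefinedStatisticError("zero variance in second matrix triangle")
    xz = (x - x.mean()) / x.std()

    def corr_with(mat: np.ndarray) -> float:
        iu = np.triu_indices(n, k=1)
        y = mat[iu]
        sy = y.std()
        if sy == 0:
            return 0.0
        return float(np.mean(xz * (y - y.mean()) / sy))

    r_obs = corr_with(m2.matrix)
    if exact:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            pm = np.asarray(perm)
            r_p = corr_with(m2.matrix[np.ix_(pm, pm)])
            count += r_p >= r_obs - 1e-12
            total += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        pm = rng.permutation(n)
        r_p = corr_with(m2.matrix[np.ix_(pm, pm)])
        count += r_p >= r_obs - 1e-12
    return r_obs, (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------- PCoA, NJ

def ibs_distance(matrix: GenotypeMatrix) -> PairwiseMatrix:
    """1 - IBS between samples; IBS = mean over co-genotyped loci of (2-|di-dj|)/2."""
    d = matrix.dosage.astype(float)
    d[matrix.dosage == MISSING] = np.nan
    n = matrix.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d[:, i:i + 1] - d[:, i + 1:])
        with np.errstate(invalid="ignore"):
            ibs = np.nanmean((2 - diff) / 2, axis=0)
        if np.isnan(ibs).any():
            j = int(np.nonzero(np.isnan(ibs))[0][0]) + i + 1
            raise ValueError(
                f"samples {matrix.samples[i]!r}/{matrix.samples[j]!r} share no "
                "genotyped locus")
        out[i, i + 1:] = out[i + 1:, i] = 1 - ibs
    return PairwiseMatrix(tuple(matrix.samples), out, kind="1-ibs")


def classical_mds(dist: PairwiseMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric scaling (PCoA) of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, keeps positive-eigenvalue axes
    ordered by eigenvalue. Returns (coordinates, explained-variance fractions).
    """
    d = dist.matrix
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-10 * abs(vals).max() if len(vals) else 0)
    vals_p, vecs_p = vals[pos], vecs[:, pos]
    coords = vecs_p * np.sqrt(vals_p)
    explained = vals_p / vals_p.sum() if vals_p.size else vals_p
    frame = pd.DataFrame(coords, index=list(dist.labels),
                         columns=[f"PCo{i+1}" for i in range(coords.shape[1])])
    return frame, explained


def pcoa(matrix: GenotypeMatrix, panel: SamplePanel | None = None
         ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCoA of samples on the 1-IBS genotype distance."""
    if matrix.n_samples < 3:
        raise ValueError("PCoA needs >= 3 samples")
    return classical_mds(ibs_distance(matrix))


def nj_tree(matrix: GenotypeMatrix, panel: SamplePanel | None = None) -> str:
    """Neighbor-joining tree (Newick) on the 1-IBS distance.

    Negative branch lengths are clamped to 0. NJ on allele-sharing distance
    stands in for likelihood phylogenetics: SNP dosages carry no substitution
    model context.
    """
    if matrix.n_samples < 3:
        raise ValueError("NJ needs >= 3 samples")
    dist = ibs_distance(matrix)
    dm = skbio.DistanceMatrix(dist.matrix, ids=list(dist.labels))
    tree = skbio.tree.nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
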