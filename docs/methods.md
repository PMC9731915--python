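# Methods

This note documents the models, estimators and design choices behind
`ambropop`, and what the synthetic-data generator does and does not emulate.

## Study design encoded by the generator

The sampling design is two regions (OH with isolation by distance, IA-MN
without), each holding 4 weedy (agricultural) and 6 wild populations of 2–5
plants, placed along a per-region transect; at least two weedy/wild pairs
per study sit within 100 m of each other (paired adjacent sites), all other
populations are kilometres apart. Two plants are sequenced twice
(biological replicate libraries) to power the SNP concordance filter.

### Genotypes

Allele frequencies follow a hierarchical Balding–Nichols model: ancestral
frequency p₀ ~ U(0.05, 0.5) per locus; each region draws
p_r ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with F = 0.05 between regions. Inside
the IBD region, populations drift *sequentially* along the transect
(a stepping-stone chain with F = 0.01 per step), so divergence grows with
separation and Mantel tests have a true signal; in the non-IBD region every
population drifts independently by F = 0.01. Genotypes are Binomial(2, p).
These defaults put pairwise Weir–Cockerham estimates on the weakly
differentiated scale the field study reports (roughly 0.002–0.11).
Balding–Nichols is a standard stand-in; it has no migration, selection or
linkage, so estimator behaviour under those forces is not tested here.

The second member of a replicate pair copies the first's genotypes, then 25
discordant singleton calls are injected into it — the targets the
concordance filter must remove, and nothing else. After the filter, all
analyses keep one library per plant (`drop_replicate_duplicates`); keeping
both would pseudo-replicate every statistic (this caused strong upward
F_ST bias in early versions and is the reason the dedup step exists).

### Expression

log2 TPM = gene baseline (N(4.5, 1.5)) + per-population effect (sd 0.3) +
module factor × loading (0.9) + noise with gene-specific sd ~ U(0.4, 0.8)
log2 units (CVs of roughly 0.3–0.8, realistic for outbred plants). The
flagged GED genes multiply the noise sd by `ged_inflation_wild` (default
2.0 — the paper gives no effect size; this is a config choice) in wild
samples only. Modules are latent-factor blocks; the last
`rewired_module_count` modules use an independent gene membership in the
wild habitat (network rewiring). DE genes get a ±2 log2FC shift in one
weedy population each. Expression is log-normal rather than count-based:
inputs are TPM and no count-level (DESeq2-style) inference is in scope.

### Sequences

Reference transcripts are random sequences with embedded ATG…stop ORFs.
Each population's collection is the reference plus planted novel
transcripts (near-zero k-mer containment elsewhere) and, for weedy
populations, region-wide homolog families: one base sequence per family,
mutated per population at 2–5 % of sites restricted to UTRs and third codon
positions with synonymous choices preferred (the purifying-selection regime
expected of conserved families — and necessary for protein-k-mer grouping
to be meaningful; unconstrained mutation at 5 % destroys ~40 % of protein
6-mers and can delete the initiator codon). The ALS-like transcript has a
620-codon ORF with CCT at codon 197 and TGG at codon 574; alternate alleles
create Ser/Leu/Phe at 197 and Leu at 574, carried by 15 % of weedy and 10 %
of wild samples (hets, 10 % of carriers homozygous) — resistance alleles
segregate in both habitats by construction, as observed in the field.

## Estimators and numerical choices

- **Weir–Cockerham F_ST** (two populations): per-locus variance components
  a, b, c from sample sizes, allele frequencies and heterozygote
  frequencies; multi-locus value is the ratio of sums Σa/Σ(a+b+c)
  (the "weighted" VCFtools behaviour). Negative per-locus components are
  retained; loci with n̄ ≤ 1 or n_c ≤ 0 or an ungenotyped population are
  skipped. Missing genotypes are excluded locus-wise, never imputed.
- **π, Ho, He**: allele-count formulas per locus, averaged over loci with
  ≥ 2 genotyped samples. On variant-only matrices π is per variant site.
- **Mantel**: Pearson correlation of lower triangles; one-sided
  (positive association); p = (1 + #{r* ≥ r})/(1 + n_perm) with joint
  row/column permutation of the second matrix; an exact mode enumerates all
  n! relabelings for small n. Ties at r are resolved with a 1e-12 slack so
  the identity permutation always counts.
- **PCoA**: distance 1 − IBS with IBS = mean over co-genotyped loci of
  (2 − |d_i − d_j|)/2 (mirrors PLINK-style allele sharing; which distance
  the original analysis used is unstated); classical double-centering and
  eigendecomposition, positive-eigenvalue axes only.
- **NJ tree**: scikit-bio's neighbor-joining on 1 − IBS, negative branch
  lengths clamped to 0. This deliberately replaces approximate-ML
  phylogenetics: SNP dosages carry no substitution-model context. The run
  manifest notes the substitution.
- **CV**: n−1 standard deviation over mean; transcripts with zero group
  mean are omitted (CV undefined at mean 0), groups of one sample skipped.
  "More than twofold" is a strict inequality on the CV ratio; the larger
  population of a pair is first downsampled (seeded, one draw by default)
  to equalize sizes.
- **Peak shifts**: Gaussian KDE (Silverman bandwidth) per habitat, local
  maxima paired greedily by proximity; pairs separated by more than 0.05 CV
  units define the interval [min − h, max + h] (h = mean bandwidth) whose
  member transcripts are reported. The original description is qualitative;
  every parameter here is exposed in the API.
- **TOM**: unsigned adjacency |pearson|^6 on log2(TPM+1) (a_ii = 0), TOM =
  (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), TOM_ii = 1.
  Zero-variance genes get correlation 0. Modules come from average-linkage
  clustering of 1 − TOM cut at height 0.97 (a static cut replaces dynamic
  tree cut), clusters of ≤ 30 genes are unassigned, ids ordered by size.
- **Module conservation**: per weedy module the best one-sided Fisher
  overlap p over wild modules on the common background, computed through
  the hypergeometric log-survival function so −log10 p is accurate far past
  float underflow (the ≥ 30 band would otherwise be unreachable). Band
  edges: ≥ 30 significant, (5, 30] moderate, [0, 5] variable; exactly 30 is
  classed significant.
- **Fisher two-sided** (allele-frequency tests): exact integer arithmetic —
  sum of all same-margin tables whose pmf numerator is ≤ the observed one.
  Integer comparison makes tie handling exact, which floating
  implementations resolve with relative tolerances.
- **Containment**: distinct canonical k-mers (lexicographic min of k-mer
  and reverse complement, k = 21 nucleotide / 6 amino acid); containment of
  a query is the fraction of its k-mers present anywhere in the target
  collection. Mapping threshold 0.8; homolog-edge threshold 0.5 on
  directional protein-k-mer containment (min denominator), families are
  connected components. These replace read mapping / assembly / BLAST
  e-values at transcript level while preserving the workflow's set logic.
- **ORFs**: longest ATG-initiated, stop-terminated frame over both strands;
  length counts codons before the stop; ≥ 100 aa retained (TransDecoder
  convention).
- **Codon annotation**: SNPs map to codon ⌈pos_in_orf/3⌉; same-codon SNPs
  are applied jointly before translation (the Pro-197-Phe double mutation);
  conservative vs nonconservative uses a 6-group amino-acid property table
  (aliphatic AVLIM, aromatic FWY, polar STNQ, positive KRH, negative DE,
  special CGP). A configurable codon offset expresses standardized
  (Arabidopsis-aligned) numbering; it must be supplied, not inferred.
- **Enrichment**: hypergeometric upper tail, BH across terms with ≥ 1
  background hit (untestable terms would inflate the correction);
  background is always the analysis's own transcript universe, not a
  genome.

## Scoring choices in the recovery tests

GED recovery aggregates the twofold filter over the study's eight
weedy–wild pairs: a planted gene counts as recovered when *any* pair flags
it, since the planted dispersion inflation applies to every wild
population. A single n=4 pair is individually underpowered — the sample CV
of the high-dispersion group is downward-skewed enough that the per-pair
hit rate stays below one half at any baseline dispersion — while the
eight-pair union recovers essentially all planted genes.

Module recovery matches each planted module to the detected weedy module
holding the majority of its genes, then checks the conservation class
(identical membership → conserved-significant; rewired → variable).

## Problem sizes

Defaults: 2 000 SNP loci, 3 000 transcripts, ~70 samples. The recovery
sweeps use 1 000 loci for the 200-seed Mantel calibration and 800
transcripts for the module-recovery seeds; the package's accuracy is
size-stable at these scales and the smaller instances keep the full test
suite and acceptance script in the minutes range on one CPU.

## Limitations

Synthetic data share none of real RNA-seq's failure modes: no mapping bias,
no expression-dependent SNP calling error, no assembly artefacts, no
library-size effects, no linkage disequilibrium, no GO DAG structure
(terms are opaque ids). Passing recovery tests shows the estimators and the
workflow logic are correct under the stated generative assumptions — not
that the biological conclusions of any particular field dataset follow.
DESeq2-style count inference, ADMIXTURE ancestry, dynamic tree cut and
BLAST statistics are intentionally out of scope; their roles are filled by
the documented stand-ins above.
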