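"""Per-habitat weighted co-expression networks and module conservation.

A simplified WGCNA-style pipeline: low-expression filter (TPM <= 1 in > 80 %
of samples), unsigned soft-threshold adjacency |cor|^beta on log2(TPM+1)
(beta = 6), topological overlap (TOM), average-linkage clustering of 1 - TOM
with a static cut, and module-size pruning (> 30 genes). Weedy modules are
then classified against wild modules by one-sided Fisher overlap, banded on
-log10 p: >= 30 conserved_significant, (5, 30] conserved_moderate,
[0, 5] variable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .datatypes import ExpressionMatrix, SamplePanel

log = logging.getLogger(__name__)

DEFAULT_BETA = 6
DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_CUT_HEIGHT = 0.97

BAND_SIGNIFICANT = 30.0
BAND_MODERATE = 5.0


def low_expression_filter(expr: ExpressionMatrix,
                          panel: SamplePanel | None = None,
                          tpm_floor: float = 1.0,
                          max_low_fraction: float = 0.80) -> ExpressionMatrix:
    """Drop transcripts with TPM <= 1 in strictly more than 80 % of samples."""
    v = expr.values
    low_frac = (v.to_numpy() <= tpm_floor).mean(axis=1)
    return ExpressionMatrix(v[low_frac <= max_low_fraction])


def adjacency_tom(expr_subset: ExpressionMatrix | pd.DataFrame,
                  beta: float = DEFAULT_BETA) -> pd.DataFrame:
    """Unsigned adjacency |pearson|^beta on log2(TPM+1), then TOM.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    a_ii = 0 and TOM_ii = 1. Zero-variance genes get correlation 0.
    """
    v = expr_subset.values if isinstance(expr_subset, ExpressionMatrix) \
        else expr_subset
    if v.shape[0] < 3 or v.shape[1] < 3:
        raise ValueError("need >= 3 genes and >= 3 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    x = np.log2(v.to_numpy(dtype=float) + 1)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x)
    cor[np.isnan(cor)] = 0.0  # zero-variance genes
    np.fill_diagonal(cor, 0.0)
    a = np.abs(cor) ** beta
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2, 0.0, 1.0)
    return pd.DataFrame(tom, index=v.index, columns=v.index)


@dataclass
class ModulePartition:
    """Gene -> module id (0 = unassigned); ids ordered by decreasing size."""

    habitat: str
    assignment: pd.Series  # index = gene, value = module id
    beta: float = DEFAULT_BETA

    @property
    def module_sizes(self) -> pd.Series:
        a = self.assignment[self.assignment > 0]
        return a.value_counts().sort_index()

    @property
    def n_modules(self) -> int:
        return int((self.assignment.value_counts().index > 0).sum())

    def genes_of(self, module_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == module_id])


def detect_modules(similarity: pd.DataFrame,
                   min_size: int = DEFAULT_MIN_MODULE_SIZE,
                   cut_height: float = DEFAULT_CUT_HEIGHT,
                   habitat: str = "", beta: float = DEFAULT_BETA
                   ) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters of size <= min_size become module 0 (unassigned) — the study
    kept only modules with more than 30 genes. Module ids are renumbered
    by decreasing size (ties broken by first gene).
    """
    genes = list(similarity.index)
    if len(genes) <= min_size:
        return ModulePartition(habitat, pd.Series(0, index=genes), beta)
    dissim = 1.0 - similarity.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    counts = pd.Series(raw).value_counts()
    keep = counts[counts > min_size]
    order = sorted(keep.index,
                   key=lambda c: (-keep[c], int(np.argmax(raw == c))))
    remap = {c: i + 1 for i, c in enumerate(order)}
    assignment = pd.Series([remap.get(c, 0) for c in raw], index=genes)
    return ModulePartition(habitat, assignment, beta)


def fisher_enrichment_neglog10(k: int, n_weedy: int, n_wild: int,
                               background: int) -> tuple[float, float]:
    """One-sided Fisher (hypergeometric upper tail) p and -log10 p for an
    overlap of k genes between a weedy module of size n_weedy and a wild
    module of size n_wild on a common background.

    Computed via the log survival function so -log10 p stays finite and
    accurate far beyond float underflow (the >= 30 band).
    """
    logsf = hypergeom.logsf(k - 1, background, n_weedy, n_wild)
    p = float(np.exp(logsf))
    neglog10 = float(-logsf / math.log(10.0)) if logsf < 0 else 0.0
    return min(p, 1.0), max(neglog10, 0.0)


@dataclass
class OverlapClassification:
    overlap: pd.DataFrame      # weedy_module, wild_module, k, p, neg_log10_p
    classes: pd.DataFrame      # weedy_module, best_wild_module, neg_log10_p, class
    background_size: int = 0

    @property
    def class_counts(self) -> pd.Series:
        return self.classes["class"].value_counts()


def classify_band(neg_log10_p: float) -> str:
    if neg_log10_p >= BAND_SIGNIFICANT:
        return "conserved_significant"
    if neg_log10_p > BAND_MODERATE:
        return "conserved_moderate"
    return "variable"


def module_overlap_classify(weedy: ModulePartition, wild: ModulePartition
                            ) -> OverlapClassification:
    """Classify each weedy module by its best Fisher overlap with any wild
    module, banded on -log10 p (>= 30 / (5, 30] / [0, 5]).

    Both partitions are restricted to their common gene background first.
    """
    common = weedy.assignment.index.intersection(wild.assignment.index)
    if len(common) < len(weedy.assignment) or len(common) < len(wild.assignment):
        log.info("module_overlap_classify: background restricted to %d common "
                 "genes", len(common))
    aw = weedy.assignment.loc[common]
    ax = wild.assignment.loc[common]
    n = len(common)
    rows = []
    for mw in sorted(set(aw[aw > 0])):
        genes_w = set(aw.index[aw == mw])
        for mx in sorted(set(ax[ax > 0])):
            genes_x = set(ax.index[ax == mx])
            k = len(genes_w & genes_x)
            p, nl = fisher_enrichment_neglog10(k, len(genes_w), len(genes_x), n)
            rows.append((mw, mx, k, p, nl))
    overlap = pd.DataFrame(rows, columns=["weedy_module", "wild_module",
                                          "overlap", "p", "neg_log10_p"])
    cls_rows = []
    for mw, sub in overlap.groupby("weedy_module"):
        best = sub.loc[sub["neg_log10_p"].idxmax()]
        cls_rows.append((mw, int(best["wild_module"]),
                         float(best["neg_log10_p"]),
                         classify_band(float(best["neg_log10_p"]))))
    classes = pd.DataFrame(cls_rows, columns=["weedy_module",
                                              "best_wild_module",
                                              "neg_log10_p", "class"])
    return OverlapClassification(overlap, classes, n)


def build_habitat_network(expr: ExpressionMatrix, panel: SamplePanel,
                          habitat: str, beta: float = DEFAULT_BETA,
                          min_size: int = DEFAULT_MIN_MODULE_SIZE,
                          cut_height: float = DEFAULT_CUT_HEIGHT
                          ) -> ModulePartition:
    """Filter, restrict to one habitat's samples, and detect modules."""
    samples = list(panel.table.loc[panel.table["habitat"] == habitat,
                                   "sample_id"])
    if len(samples) < 3:
        raise ValueError(f"habitat {habitat!r} has < 3 samples")
    filtered = low_expression_filter(expr)
    sub = filtered.subset_samples(samples)
    tom = adjacency_tom(sub, beta=beta)
    return detect_modules(tom, min_size=min_size, cut_height=cut_height,
                          habitat=habitat, beta=beta)
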