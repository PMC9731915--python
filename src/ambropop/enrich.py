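"""Hypergeometric term enrichment with Benjamini-Hochberg correction."""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import AnnotationMap


def enrich(gene_set: Iterable[str], background: Iterable[str],
           annotation: AnnotationMap, alpha: float = 0.05) -> pd.DataFrame:
    """Term over-representation in ``gene_set`` relative to ``background``.

    Upper-tail hypergeometric p = P(X >= k | N, K, n) per term, BH-adjusted
    across all terms with at least one background hit (terms no background
    gene carries are untestable and excluded before correction).

    Returns a frame sorted by adjusted p with columns term_id, description,
    k, K, n, N, gene_ratio, p, p_adj, significant.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    gs = set(gene_set)
    if not gs <= bg:
        raise ValueError("gene_set must be a subset of background")
    term_bg: dict[str, int] = {}
    term_hits: dict[str, int] = {}
    for gene in bg:
        for term in annotation.of(gene):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in gs:
                term_hits[term] = term_hits.get(term, 0) + 1
    n_bg, n_set = len(bg), len(gs)
    rows = []
    for term, big_k in sorted(term_bg.items()):
        k = term_hits.get(term, 0)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_set))
        rows.append((term, annotation.descriptions.get(term, term), k, big_k,
                     n_set, n_bg, k / n_set if n_set else 0.0, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term_id", "description", "k", "K", "n",
                                     "N", "gene_ratio", "p"])
    if df.empty:
        df["p_adj"] = []
        df["significant"] = []
        return df
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["p_adj"] <= alpha
    return df.sort_values(["p_adj", "p", "term_id"]).reset_index(drop=True)
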