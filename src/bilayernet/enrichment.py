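"""Hypergeometric gene-set over-representation analysis.

A local stand-in for web-service KEGG enrichment: for a query gene list and
a collection of gene sets over a background universe of N genes, the
p-value of a pathway with K members and k overlapping query genes out of an
n-gene query is the hypergeometric upper tail P(X >= k).  Pathways with raw
p below the threshold (default 0.05) are flagged; BH-adjusted values are
reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection
from .differential import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "hypergeometric_enrichment", "enrichment_frame"]

ENRICH_P = 0.05


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    k_overlap: int
    K_pathway: int
    n_query: int
    N_background: int
    p_value: float
    fdr: float
    gene_ratio: float
    significant: bool
    overlap_genes: tuple[str, ...]


def hypergeometric_enrichment(
    query_genes,
    sets: GeneSetCollection,
    p_threshold: float = ENRICH_P,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of each pathway against the query.

    Query genes outside the background are dropped with a warning; an empty
    query or background is an error.  Results are sorted by p-value, ties by
    pathway ID.
    """
    if not sets.background:
        raise ValueError("empty background universe")
    query = set(query_genes)
    if not query:
        raise ValueError("empty query gene list")
    outside = query - sets.background
    if outside:
        logger.warning("%d query genes outside the background dropped", len(outside))
        query -= outside
    if not query:
        raise ValueError("no query genes left inside the background")

    N = len(sets.background)
    n = len(query)
    rows: list[EnrichmentResult] = []
    for pid, (name, genes) in sets.sets.items():
        overlap = query & genes
        k = len(overlap)
        K = len(genes)
        # P(X >= k) for X ~ Hypergeometric(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            EnrichmentResult(
                pathway_id=pid,
                pathway_name=name,
                k_overlap=k,
                K_pathway=K,
                n_query=n,
                N_background=N,
                p_value=min(p, 1.0),
                fdr=1.0,
                gene_ratio=k / n,
                significant=False,
                overlap_genes=tuple(sorted(overlap)),
            )
        )
    if rows:
        fdrs = benjamini_hochberg([r.p_value for r in rows])
        for r, q in zip(rows, fdrs):
            r.fdr = float(q)
            r.significant = r.p_value < p_threshold
    rows.sort(key=lambda r: (r.p_value, r.pathway_id))
    return rows


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Dot-plot-ready table: count, gene ratio, -log10 p per pathway."""
    import numpy as np

    df = pd.DataFrame([vars(r) for r in results])
    if not df.empty:
        df["overlap_genes"] = df["overlap_genes"].map(lambda t: ",".join(t))
        df["neg_log10_p"] = -np.log10(df["p_value"].clip(lower=1e-300))
    return df
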