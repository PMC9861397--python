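"""Bilayer network construction.

The methylation layer links two differential sites when the Pearson
correlation of their β values across tumor samples satisfies |r| > 0.8
(strict).  The RNA layer is the undirected graph of high-confidence RNA-RNA
interactions.  A methylation edge survives into the bilayer network only if
its two sites are inter-layer consistent, i.e. some annotated gene pair
(g_a, g_b) across the two sites satisfies one of

  i   same gene:        g_a == g_b
  ii  direct edge:      (g_a, g_b) is an RNA-layer edge
  iii shared neighbor:  g_a and g_b have a common RNA-layer neighbor
                        (graph distance exactly 2, typically through a
                        noncoding bridge RNA)

Edges failing all three are removed however strong the correlation — the
point of the construction.  The admitting condition is recorded per edge
with precedence i > ii > iii.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datatypes import BetaMatrix, RnaInteractionTable, SiteGeneMap

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_r",
    "build_methylation_layer",
    "build_rna_layer",
    "admissible",
    "filter_methylation_edges",
    "BilayerNetwork",
]

CORR_CUTOFF = 0.8

SAME_GENE = "same_gene"
DIRECT_EDGE = "direct_edge"
SHARED_NEIGHBOR = "shared_neighbor"
NONE = "none"


def pearson_r(x, y) -> float:
    """Pearson correlation of two sample vectors; NaN if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need 1-D vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def build_methylation_layer(
    beta: BetaMatrix,
    sites: list[str] | None = None,
    cutoff: float = CORR_CUTOFF,
    block_size: int = 2000,
) -> nx.Graph:
    """All-pairs |r| > cutoff correlation graph over tumor samples.

    Correlations are exact, computed blockwise to bound memory; ``sites``
    restricts the node universe (typically the differential sites).  Every
    requested site becomes a node even if it gains no edge.
    """
    tumor = beta.tumor_values()
    if tumor.shape[1] < 3:
        raise ValueError("need at least 3 tumor samples to correlate sites")
    if sites is None:
        sites = beta.site_ids
    else:
        missing = set(sites) - set(beta.site_ids)
        if missing:
            raise ValueError(f"sites absent from β matrix: {sorted(missing)[:5]}")
    graph = nx.Graph()
    graph.add_nodes_from(sites)
    if len(sites) < 2:
        return graph

    data = tumor.loc[sites].to_numpy(dtype=float)
    # standardize rows once; constant rows get a zero std guard (no edges)
    mean = data.mean(axis=1, keepdims=True)
    centered = data - mean
    norms = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    constant = norms[:, 0] == 0
    if constant.any():
        logger.warning("%d constant sites excluded from correlation edges", int(constant.sum()))
    norms[constant] = 1.0
    z = centered / norms
    z[constant] = 0.0

    n = len(sites)
    for i0 in range(0, n, block_size):
        i1 = min(i0 + block_size, n)
        for j0 in range(i0, n, block_size):
            j1 = min(j0 + block_size, n)
            block = z[i0:i1] @ z[j0:j1].T
            ii, jj = np.nonzero(np.abs(block) > cutoff)
            for a, b in zip(ii, jj):
                gi, gj = i0 + int(a), j0 + int(b)
                if gi < gj:
                    graph.add_edge(sites[gi], sites[gj], r=float(np.clip(block[a, b], -1, 1)))
    return graph


def build_rna_layer(table: RnaInteractionTable) -> nx.Graph:
    """Undirected RNA graph with per-node ``rna_type`` and per-edge confidence."""
    graph = nx.Graph()
    types = table.node_types
    for node, rna_type in types.items():
        graph.add_node(node, rna_type=rna_type)
    for _, row in table.rows.iterrows():
        graph.add_edge(row["rna_a"], row["rna_b"], confidence=float(row["confidence"]))
    return graph


def admissible(
    site_a: str, site_b: str, sgmap: SiteGeneMap, rna: nx.Graph
) -> tuple[bool, str]:
    """Inter-layer admissibility of a site pair, with the admitting condition.

    Checks every annotated gene pair across the two sites (most permissive
    many-to-many reading); condition precedence same_gene > direct_edge >
    shared_neighbor.  Unmapped sites yield (False, "none").
    """
    genes_a = sgmap.genes_of(site_a)
    genes_b = sgmap.genes_of(site_b)
    if not genes_a or not genes_b:
        logger.warning("site pair (%s, %s) has an unannotated member", site_a, site_b)
        return False, NONE
    if genes_a & genes_b:
        return True, SAME_GENE
    for ga in genes_a:
        if ga in rna:
            for gb in genes_b:
                if rna.has_edge(ga, gb):
                    return True, DIRECT_EDGE
    for ga in genes_a:
        if ga not in rna:
            continue
        na = set(rna.adj[ga])
        for gb in genes_b:
            if gb in rna and na & set(rna.adj[gb]):
                return True, SHARED_NEIGHBOR
    return False, NONE


@dataclass
class BilayerNetwork:
    """The filtered methylation layer coupled to the RNA layer."""

    methylation: nx.Graph  # post-filter; edges carry r and condition
    rna: nx.Graph
    site_gene_map: SiteGeneMap
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)
    removed_edges: int = 0

    @property
    def unmapped_sites(self) -> list[str]:
        return [s for s in self.methylation.nodes if not self.site_gene_map.genes_of(s)]

    def summary(self) -> dict:
        conditions = {}
        for cond in (SAME_GENE, DIRECT_EDGE, SHARED_NEIGHBOR):
            conditions[cond] = sum(1 for c in self.provenance.values() if c == cond)
        return {
            "methylation_nodes": self.methylation.number_of_nodes(),
            "methylation_edges": self.methylation.number_of_edges(),
            "rna_nodes": self.rna.number_of_nodes(),
            "rna_edges": self.rna.number_of_edges(),
            "removed_edges": self.removed_edges,
            "retained_by_condition": conditions,
        }


def filter_methylation_edges(
    layer: nx.Graph, sgmap: SiteGeneMap, rna: nx.Graph
) -> BilayerNetwork:
    """Apply the three-condition inter-layer filter to a correlation layer.

    Exactly the admissible edges are retained; nodes stay in place even when
    isolated, keeping the node universe stable for top-k comparisons.
    """
    filtered = nx.Graph()
    filtered.add_nodes_from(layer.nodes)
    provenance: dict[tuple[str, str], str] = {}
    removed = 0
    for a, b, attrs in layer.edges(data=True):
        ok, condition = admissible(a, b, sgmap, rna)
        if ok:
            key = (a, b) if a <= b else (b, a)
            attrs = {k: v for k, v in attrs.items() if k != "condition"}
            filtered.add_edge(a, b, condition=condition, **attrs)
            provenance[key] = condition
        else:
            removed += 1
    logger.info(
        "inter-layer filter: kept %d of %d edges (%d removed)",
        filtered.number_of_edges(), layer.number_of_edges(), removed,
    )
    return BilayerNetwork(
        methylation=filtered,
        rna=rna,
        site_gene_map=sgmap,
        provenance=provenance,
        removed_edges=removed,
    )
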