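"""Network indicators: centralities, clustering, path lengths, ER baselines.

Conventions:

* degree centrality is degree/(N-1); betweenness is the unnormalized sum
  over unordered pairs of shortest-path fractions with endpoints excluded;
* nodes of degree < 2 get clustering coefficient 0 (configurable to be
  excluded from the average);
* the average path length is the mean distance over unordered pairs of
  distinct nodes within the same connected component — cross-component
  pairs are excluded, the only computable convention on a disconnected
  graph;
* the Erdős–Rényi baselines for a graph with N nodes and average degree
  <k> are path length ln N and clustering <k>/(N-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "average_degree",
    "average_degree_from_counts",
    "clustering_coefficient",
    "average_path_length",
    "er_baselines",
    "er_path_length",
    "degree_distribution",
    "centrality_table",
    "network_summary",
    "NetworkSummary",
]


def degree_centrality(graph: nx.Graph) -> dict[str, float]:
    """degree/(N-1) per node."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("degree centrality needs at least 2 nodes")
    return {v: d / (n - 1) for v, d in graph.degree()}


def betweenness_centrality(graph: nx.Graph) -> dict[str, float]:
    """Unnormalized betweenness (sum over unordered pairs, endpoints excluded).

    Uses the standard single-source shortest-path accumulation; exact, never
    sampled.
    """
    return nx.betweenness_centrality(graph, normalized=False)


def average_degree(graph: nx.Graph) -> float:
    """2E/N — the mean node degree."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("average degree of the empty graph is undefined")
    return 2.0 * graph.number_of_edges() / n


def average_degree_from_counts(n_nodes: int, n_edges: int) -> float:
    """2E/N from a node/edge census alone."""
    if n_nodes <= 0:
        raise ValueError("need a positive node count")
    return 2.0 * n_edges / n_nodes


def clustering_coefficient(
    graph: nx.Graph, include_low_degree: bool = True
) -> tuple[dict[str, float], float]:
    """Per-node C_i = 2 E_i / (k_i (k_i - 1)) and the network average.

    Nodes with k_i < 2 get C_i = 0; ``include_low_degree`` controls whether
    they enter the average.
    """
    per_node = nx.clustering(graph)  # networkx assigns 0 when k_i < 2
    per_node = {v: float(c) for v, c in per_node.items()}
    if include_low_degree:
        pool = list(per_node.values())
    else:
        pool = [c for v, c in per_node.items() if graph.degree(v) >= 2]
    avg = float(np.mean(pool)) if pool else 0.0
    return per_node, avg


def average_path_length(graph: nx.Graph) -> float:
    """Mean shortest-path length over connected unordered distinct pairs."""
    total = 0.0
    pairs = 0
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        sub = graph.subgraph(comp)
        m = len(comp)
        total += nx.average_shortest_path_length(sub) * (m * (m - 1) / 2)
        pairs += m * (m - 1) // 2
    if pairs == 0:
        raise ValueError("graph has no connected pair of nodes")
    return total / pairs


def er_path_length(n_nodes: int) -> float:
    """ER random-graph path-length baseline, ln N."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return float(np.log(n_nodes))


def er_baselines(n_nodes: int, avg_degree: float) -> tuple[float, float]:
    """(er_clustering, er_path_length) for a matched random graph.

    Clustering is the edge probability <k>/(N-1); path length is ln N.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return avg_degree / (n_nodes - 1), er_path_length(n_nodes)


def degree_distribution(graph: nx.Graph) -> dict:
    """Degree histogram plus a mean-vs-median right-skew flag."""
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    if len(degrees) == 0:
        return {"histogram": {}, "mean": 0.0, "median": 0.0, "right_skewed": False}
    values, counts = np.unique(degrees.astype(int), return_counts=True)
    return {
        "histogram": {int(v): int(c) for v, c in zip(values, counts)},
        "mean": float(degrees.mean()),
        "median": float(np.median(degrees)),
        "right_skewed": bool(degrees.mean() > np.median(degrees)),
    }


def centrality_table(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree centrality, betweenness centrality and raw degree."""
    dc = degree_centrality(graph)
    bc = betweenness_centrality(graph)
    nodes = sorted(graph.nodes)
    return pd.DataFrame(
        {
            "node": nodes,
            "raw_degree": [graph.degree(v) for v in nodes],
            "degree_centrality": [dc[v] for v in nodes],
            "betweenness_centrality": [bc[v] for v in nodes],
        }
    ).set_index("node")


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_clustering: float
    average_path_length: float | None
    er_clustering: float
    er_path_length: float

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "average_degree": self.average_degree,
            "average_clustering": self.average_clustering,
            "average_path_length": self.average_path_length,
            "er_clustering": self.er_clustering,
            "er_path_length": self.er_path_length,
        }


def network_summary(graph: nx.Graph) -> NetworkSummary:
    """The Table-1-style census of a layer."""
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    avg_k = average_degree(graph)
    _, avg_c = clustering_coefficient(graph)
    try:
        apl = average_path_length(graph)
    except ValueError:
        apl = None
    er_c, er_l = er_baselines(n, avg_k) if n >= 2 else (0.0, 0.0)
    return NetworkSummary(n, e, avg_k, avg_c, apl, er_c, er_l)
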