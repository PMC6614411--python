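"""Gene-interaction network analysis: score filtering, degree, edge
betweenness (Brandes), and hub identification.

Edges carry a combined confidence score in [0, 1] (STRING-style); only
edges strictly above the confidence threshold (default 0.7) enter the
graph.  Scores are used for filtering only — shortest paths are
unweighted, matching common practice for interaction networks.  Edge
betweenness counts, for each unordered node pair, the fraction of that
pair's shortest paths traversing the edge; hub nodes are the
highest-degree nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import networkx as nx
import pandas as pd

__all__ = [
    "build_graph",
    "degree_and_betweenness",
    "identify_hubs",
    "NetworkMetrics",
    "read_edge_list",
    "DEFAULT_SCORE_THRESHOLD",
    "DEFAULT_HUB_COUNT",
]

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 0.7
#: hub-list length convention (the analyses this mirrors name ~8 hub genes)
DEFAULT_HUB_COUNT = 8


def read_edge_list(path) -> pd.DataFrame:
    """Read a TSV edge list (gene_a, gene_b, combined_score).

    Malformed rows are skipped and counted in the log.
    """
    rows: List[Tuple[str, str, float]] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 0 and parts[:2] == ["gene_a", "gene_b"]:
                continue
            try:
                a, b, score = parts[0], parts[1], float(parts[2])
            except (IndexError, ValueError):
                skipped += 1
                continue
            rows.append((a, b, score))
    if skipped:
        logger.warning("skipped %d malformed edge rows", skipped)
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])


def build_graph(edges: pd.DataFrame, threshold: float = DEFAULT_SCORE_THRESHOLD) -> nx.Graph:
    """Undirected graph of edges with combined_score strictly above the
    threshold; self-loops dropped, duplicate pairs deduplicated keeping
    the maximum score, isolated nodes omitted."""
    bad = edges[(edges["combined_score"] < 0) | (edges["combined_score"] > 1)]
    if len(bad):
        raise ValueError("combined scores must lie in [0, 1]")
    g = nx.Graph()
    kept = edges[edges["combined_score"] > threshold]
    for a, b, score in kept[["gene_a", "gene_b", "combined_score"]].itertuples(index=False):
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], score)
        else:
            g.add_edge(a, b, combined_score=float(score))
    return g


@dataclass(frozen=True)
class NetworkMetrics:
    degree: Dict[str, int]
    edge_betweenness: Dict[Tuple[str, str], float]
    hubs: List[str]


def degree_and_betweenness(
    g: nx.Graph, fractional: bool = True
) -> NetworkMetrics:
    """Degree, edge betweenness and the full degree-ranked hub ordering.

    Betweenness uses Brandes' algorithm over unweighted shortest paths;
    with ``fractional=True`` (default) a pair with several equally short
    paths contributes 1/σ to each, otherwise every tied path counts as a
    full unit.  Hubs are ranked by degree descending, id ascending on
    ties.
    """
    degree = {node: int(d) for node, d in g.degree()}
    if fractional:
        raw = nx.edge_betweenness_centrality(g, normalized=False)
        betweenness = {_norm_edge(e): float(v) for e, v in raw.items()}
    else:
        betweenness = _integer_betweenness(g)
    hubs = sorted(degree, key=lambda node: (-degree[node], node))
    return NetworkMetrics(degree=degree, edge_betweenness=betweenness, hubs=hubs)


def _norm_edge(e: Tuple[str, str]) -> Tuple[str, str]:
    a, b = e
    return (a, b) if a <= b else (b, a)


def _integer_betweenness(g: nx.Graph) -> Dict[Tuple[str, str], float]:
    """Count every tied shortest path as a full unit (no 1/σ weighting)."""
    counts: Dict[Tuple[str, str], float] = {_norm_edge(e): 0.0 for e in g.edges()}
    nodes = sorted(g.nodes())
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if not nx.has_path(g, s, t):
                continue
            for path in nx.all_shortest_paths(g, s, t):
                for u, v in zip(path, path[1:]):
                    counts[_norm_edge((u, v))] += 1.0
    return counts


def identify_hubs(metrics: NetworkMetrics, k: int = DEFAULT_HUB_COUNT) -> List[str]:
    """Top-k nodes by degree (ties broken by id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(metrics.hubs):
        logger.warning("requested %d hubs but graph has only %d nodes", k, len(metrics.hubs))
    return metrics.hubs[:k]
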