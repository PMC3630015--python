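"""Bipartite relevance networks thresholded from a similarity matrix.

An edge joins X^j and Y^k whenever |M[j, k]| >= threshold (the boundary is
inclusive, so a printed threshold like 0.5 keeps entries equal to 0.5);
variables without any edge are dropped entirely, so the graph never holds
isolated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .similarity import SimilarityMatrix

__all__ = ["RelevanceNetwork", "build_network", "connected_components", "export_network"]


@dataclass(frozen=True)
class RelevanceNetwork:
    """Thresholded bipartite graph over X- and Y-variables.

    ``edges`` holds (x_id, y_id, weight) triples; node sets contain only
    edge endpoints.
    """

    x_nodes: list[str]
    y_nodes: list[str]
    edges: list[tuple[str, str, float]]
    threshold: float

    @property
    def n_nodes(self) -> int:
        return len(self.x_nodes) + len(self.y_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(threshold=self.threshold)
        for xid in self.x_nodes:
            g.add_node(xid, side="X")
        for yid in self.y_nodes:
            g.add_node(yid, side="Y")
        for xid, yid, w in self.edges:
            g.add_edge(xid, yid, weight=float(w), sign="+" if w >= 0 else "-")
        return g


def build_network(m: SimilarityMatrix, threshold: float) -> RelevanceNetwork:
    """Keep every pair with |M[j, k]| >= threshold; drop isolated nodes."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    keep = np.abs(m.values) >= threshold
    rows, cols = np.nonzero(keep)
    edges = [
        (m.x_ids[j], m.y_ids[k], float(m.values[j, k])) for j, k in zip(rows, cols)
    ]
    x_nodes = [m.x_ids[j] for j in np.unique(rows)]
    y_nodes = [m.y_ids[k] for k in np.unique(cols)]
    return RelevanceNetwork(x_nodes, y_nodes, edges, float(threshold))


def connected_components(net: RelevanceNetwork) -> list[set[str]]:
    """Connected components, ordered by their lexicographically smallest
    member id (deterministic)."""
    comps = nx.connected_components(net.to_networkx())
    return sorted((set(c) for c in comps), key=lambda c: min(c))


def export_network(net: RelevanceNetwork, path, fmt: str = "graphml") -> None:
    """Write GraphML (node attribute ``side``; edge attributes ``weight``
    and ``sign``) or whitespace-delimited SIF with interaction labels
    pos/neg."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif fmt == "sif":
        lines = [
            f"{xid} {'pos' if w >= 0 else 'neg'} {yid}"
            for xid, yid, w in net.edges
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown export format {fmt!r}; use 'graphml' or 'sif'")
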