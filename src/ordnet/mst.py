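"""Minimum spanning tree backbone of a partial-correlation network.

Edges are converted to distances by Gower's similarity-to-distance
transform ``d = sqrt(2 (1 - w))`` applied to the signed partial
correlation (an ``absolute=True`` switch uses |w| instead). Because a zero
weight maps to the finite distance sqrt(2), the distance graph is complete
and a spanning tree always exists. The tree itself comes from Kruskal's
algorithm with union-find and deterministic lexicographic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ggm import NetworkModel

__all__ = ["SpanningTree", "gower_distance", "kruskal_mst", "mst_backbone"]


@dataclass
class SpanningTree:
    """p-1 edges connecting all nodes without cycles."""

    edges: list[tuple[int, int, float, float]]  # (i, j, distance, weight)
    total_distance: float
    node_labels: list[str]

    @property
    def p(self) -> int:
        return len(self.node_labels)

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            (self.node_labels[i], self.node_labels[j], d, w)
            for i, j, d, w in self.edges
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "distance", "weight"])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        for i, j, d, w in self.edges:
            g.add_edge(
                self.node_labels[i], self.node_labels[j], distance=d, weight=w
            )
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def gower_distance(network: NetworkModel, absolute: bool = False) -> np.ndarray:
    """Distance matrix d_ij = sqrt(2 (1 - w_ij)), zero diagonal.

    With ``absolute=True`` the transform is applied to |w| so that strong
    negative edges also count as close.
    """
    w = np.abs(network.weights) if absolute else network.weights
    d = np.sqrt(np.clip(2.0 * (1.0 - w), 0.0, None))
    np.fill_diagonal(d, 0.0)
    return d


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def kruskal_mst(
    distances: np.ndarray,
    labels: list[str] | None = None,
    weights: np.ndarray | None = None,
) -> SpanningTree:
    """Kruskal's MST over a complete symmetric distance matrix.

    Ties are broken by lexicographic node-pair order, so the tree is
    deterministic. ``weights`` (optional, same shape) is carried through to
    the edge records for reporting the original partial correlations.
    """
    d = np.asarray(distances, dtype=float)
    p = d.shape[0]
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    labels = labels or [f"V{i + 1}" for i in range(p)]
    pairs = [(d[i, j], i, j) for i in range(p) for j in range(i + 1, p)]
    pairs.sort()  # (distance, i, j): lexicographic tie-break built in
    uf = _UnionFind(p)
    edges: list[tuple[int, int, float, float]] = []
    for dist, i, j in pairs:
        if uf.union(i, j):
            w = float(weights[i, j]) if weights is not None else np.nan
            edges.append((i, j, float(dist), w))
            if len(edges) == p - 1:
                break
    return SpanningTree(
        edges=edges,
        total_distance=float(sum(e[2] for e in edges)),
        node_labels=list(labels),
    )


def mst_backbone(network: NetworkModel, absolute: bool = False) -> SpanningTree:
    """Convenience wrapper: Gower distances then Kruskal."""
    d = gower_distance(network, absolute=absolute)
    return kruskal_mst(d, labels=network.node_labels, weights=network.weights)
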