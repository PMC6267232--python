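"""Minimum spanning tree of PLI matrices and global tree topology metrics.

"Minimum spanning tree based on the PLI" means the maximum-total-PLI tree:
the strongest connections form the backbone, equivalently the minimum
spanning tree of any strictly decreasing transform of PLI (e.g. 1 - PLI).
Kruskal's algorithm is run on edges sorted by descending weight with ties
broken by lexicographic (i, j) pair order, so the tree is deterministic
even when finite-sample PLI values collide.

Metrics (m = N - 1 edges, L = number of leaves):

==================  =====================================================
degree_max          max node degree / m
leaf_fraction       L / m
eccentricity_mean   mean over nodes of hop eccentricity / m
bc_max              max betweenness centrality / ((N-1)(N-2)/2)
tree_hierarchy      T_H = L / (2 m BC_max), BC_max normalized as above
==================  =====================================================

A star therefore has leaf_fraction = degree_max = bc_max = 1 and
T_H = 0.5; a long path has leaf_fraction = 2/m and T_H -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import networkx as nx
import numpy as np

from .connectivity import AdjacencyMatrix
from .errors import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class SpanningTree:
    """An acyclic connected subgraph with exactly n_nodes - 1 edges."""

    n_nodes: int
    edges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple((int(i), int(j), float(w)) for i, j, w in self.edges))
        if len(self.edges) != self.n_nodes - 1:
            raise ValidationError(
                f"tree on {self.n_nodes} nodes needs {self.n_nodes - 1} edges, "
                f"got {len(self.edges)}"
            )
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for i, j, _ in self.edges:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValidationError(f"edge ({i}, {j}) out of range")
            g.add_edge(i, j)
        if g.number_of_edges() != self.n_nodes - 1 or not nx.is_connected(g):
            raise ValidationError("edges do not form a spanning tree")

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class MstMetrics:
    degree_max: float
    leaf_fraction: float
    eccentricity_mean: float
    bc_max: float
    tree_hierarchy: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


METRIC_NAMES: tuple[str, ...] = tuple(f.name for f in fields(MstMetrics))


class _UnionFind:
    def __init__(self, n: int) -> None:
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


def build_mst(adj: AdjacencyMatrix | np.ndarray) -> SpanningTree:
    """Maximum-weight spanning tree by Kruskal, deterministic under ties.

    Stored edge weights are the original PLI values.
    """
    values = adj.values if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 nodes")
    if values.shape != (n, n) or not np.allclose(values, values.T, atol=1e-12, rtol=0.0):
        raise ValidationError("adjacency must be square and symmetric")
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    # stable sort on descending weight keeps lexicographic (i, j) order
    # among equal weights because (iu, ju) is generated in that order
    order = np.argsort(-w, kind="stable")
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            edges.append((i, j, float(w[k])))
            if len(edges) == n - 1:
                break
    return SpanningTree(n_nodes=n, edges=tuple(edges))


def mst_metrics(tree: SpanningTree) -> MstMetrics:
    """The five global tree metrics under the module's fixed normalizations."""
    n = tree.n_nodes
    if n < 3:
        raise DegenerateInputError(
            "betweenness normalization is undefined for a 2-node tree"
        )
    g = tree.to_graph()
    m = n - 1
    degrees = np.array([d for _, d in g.degree()])
    leaves = int((degrees == 1).sum())
    ecc = nx.eccentricity(g)  # hop counts: unweighted paths
    bc = nx.betweenness_centrality(g, normalized=True, weight=None)
    bc_max = float(max(bc.values()))
    if bc_max == 0.0:
        raise DegenerateInputError("max betweenness is 0; tree hierarchy undefined")
    return MstMetrics(
        degree_max=float(degrees.max()) / m,
        leaf_fraction=leaves / m,
        eccentricity_mean=float(np.mean(list(ecc.values()))) / m,
        bc_max=bc_max,
        tree_hierarchy=leaves / (2.0 * m * bc_max),
    )


def subject_mst_profile(per_epoch: list[AdjacencyMatrix]) -> MstMetrics:
    """Per-epoch MST metrics averaged arithmetically across epochs.

    Metrics are computed on each epoch's own tree and then averaged — not
    computed on an averaged matrix, which would be a different (nonlinear)
    quantity.
    """
    if not per_epoch:
        raise ValidationError("need at least one epoch matrix")
    profiles = [mst_metrics(build_mst(adj)) for adj in per_epoch]
    return MstMetrics(
        **{
            name: float(np.mean([getattr(p, name) for p in profiles]))
            for name in METRIC_NAMES
        }
    )
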