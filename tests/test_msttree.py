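import itertools

import networkx as nx
import numpy as np
import pytest

from mnc.errors import DegenerateInputError, ValidationError
from mnc.msttree import (
    METRIC_NAMES,
    MstMetrics,
    SpanningTree,
    build_mst,
    mst_metrics,
    subject_mst_profile,
)
from mnc.connectivity import AdjacencyMatrix
from mnc.spectral import DEFAULT_BANDS

THETA = DEFAULT_BANDS[0]


def symmetric_matrix(rng, n, unique=True):
    iu = np.triu_indices(n, 1)
    w = rng.uniform(0.01, 0.99, size=len(iu[0]))
    if unique:
        while len(np.unique(w)) != len(w):  # pragma: no cover
            w = rng.uniform(0.01, 0.99, size=len(iu[0]))
    m = np.zeros((n, n))
    m[iu] = w
    return m + m.T


def bruteforce_max_tree_weight(values):
    """Enumerate every labeled spanning tree and return the max total weight."""
    n = values.shape[0]
    all_edges = list(itertools.combinations(range(n), 2))
    best = -np.inf
    for subset in itertools.combinations(all_edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(subset)
        if nx.is_connected(g):
            best = max(best, sum(values[i, j] for i, j in subset))
    return best


def star_tree(n):
    return SpanningTree(n, tuple((0, i, 1.0) for i in range(1, n)))


def path_tree(n):
    return SpanningTree(n, tuple((i, i + 1, 1.0) for i in range(n - 1)))


class TestBuildMst:
    def test_obvious_maximum_tree(self):
        v = np.array([[0, 0.9, 0.1], [0.9, 0, 0.8], [0.1, 0.8, 0]])
        tree = build_mst(v)
        assert sorted((i, j) for i, j, _ in tree.edges) == [(0, 1), (1, 2)]
        assert tree.total_weight() == pytest.approx(1.7)

    def test_hub_matrix_gives_star(self):
        n = 8
        v = np.full((n, n), 0.1)
        v[0, :] = v[:, 0] = 0.9
        np.fill_diagonal(v, 0.0)
        tree = build_mst(v)
        degrees = np.zeros(n, int)
        for i, j, _ in tree.edges:
            degrees[i] += 1
            degrees[j] += 1
        assert degrees[0] == n - 1

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 8))
            v = symmetric_matrix(rng, n)
            assert build_mst(v).total_weight() == pytest.approx(
                bruteforce_max_tree_weight(v), abs=1e-12
            )

    def test_matches_networkx_maximum_spanning_tree(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 12))
            v = symmetric_matrix(rng, n)
            g = nx.from_numpy_array(v)
            expected = nx.maximum_spanning_tree(g, algorithm="kruskal").size(
                weight="weight"
            )
            assert build_mst(v).total_weight() == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        for _ in range(10):
            v = symmetric_matrix(rng, 9)
            direct = {tuple(sorted((i, j))) for i, j, _ in build_mst(v).edges}
            # distance form: minimum tree of 1/(w+eps) == maximum tree of w
            d = 1.0 / (v + 1e-6)
            np.fill_diagonal(d, 0.0)
            g = nx.from_numpy_array(d)
            alt = {
                tuple(sorted(e))
                for e in nx.minimum_spanning_tree(g, algorithm="kruskal").edges()
            }
            assert direct == alt

    def test_tie_breaking_is_deterministic(self):
        v = np.full((5, 5), 0.5)
        np.fill_diagonal(v, 0.0)
        t1 = build_mst(v)
        t2 = build_mst(v)
        assert t1.edges == t2.edges
        # lexicographic pair order: node 0 connects to everyone
        assert [(i, j) for i, j, _ in t1.edges] == [(0, 1), (0, 2), (0, 3), (0, 4)]

    def test_accepts_adjacency_matrix(self, rng):
        v = symmetric_matrix(rng, 5) / 2.0
        adj = AdjacencyMatrix(v, THETA, tuple("ABCDE"))
        tree = build_mst(adj)
        assert tree.n_nodes == 5

    def test_too_small_rejected(self):
        with pytest.raises(ValidationError):
            build_mst(np.zeros((1, 1)))


class TestSpanningTreeInvariants:
    def test_wrong_edge_count_rejected(self):
        with pytest.raises(ValidationError):
            SpanningTree(4, ((0, 1, 1.0), (2, 3, 1.0)))

    def test_cycle_rejected(self):
        with pytest.raises(ValidationError):
            SpanningTree(4, ((0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)))


def bruteforce_metrics(tree: SpanningTree) -> MstMetrics:
    """Independent recomputation via explicit path enumeration (BFS by hand)."""
    n = tree.n_nodes
    adj = {i: [] for i in range(n)}
    for i, j, _ in tree.edges:
        adj[i].append(j)
        adj[j].append(i)

    def bfs_paths(src):
        parent = {src: None}
        queue = [src]
        for node in queue:
            for nb in adj[node]:
                if nb not in parent:
                    parent[nb] = node
                    queue.append(nb)
        return parent

    dist = np.zeros((n, n), int)
    through = np.zeros(n)
    for a in range(n):
        parent = bfs_paths(a)
        for b in range(a + 1, n):
            path = [b]
            while path[-1] != a:
                path.append(parent[path[-1]])
            dist[a, b] = dist[b, a] = len(path) - 1
            for interior in path[1:-1]:
                through[interior] += 1
    m = n - 1
    degrees = np.array([len(adj[i]) for i in range(n)])
    leaves = int((degrees == 1).sum())
    bc_max = through.max() / (((n - 1) * (n - 2)) / 2.0)
    return MstMetrics(
        degree_max=degrees.max() / m,
        leaf_fraction=leaves / m,
        eccentricity_mean=dist.max(axis=1).mean() / m,
        bc_max=bc_max,
        tree_hierarchy=leaves / (2.0 * m * bc_max),
    )


class TestMstMetrics:
    def test_star_closed_form(self):
        got = mst_metrics(star_tree(10))
        assert got.leaf_fraction == pytest.approx(1.0)
        assert got.degree_max == pytest.approx(1.0)
        assert got.bc_max == pytest.approx(1.0)
        assert got.tree_hierarchy == pytest.approx(0.5)
        # every leaf at 2 hops from another leaf, hub at 1: mean ecc = (1 + 9*2)/10
        assert got.eccentricity_mean == pytest.approx((1 + 9 * 2) / 10 / 9)

    def test_path_closed_form(self):
        got = mst_metrics(path_tree(10))
        assert got.leaf_fraction == pytest.approx(2 / 9)
        assert got.degree_max == pytest.approx(2 / 9)

    def test_path_hierarchy_decreases_with_length(self):
        values = [mst_metrics(path_tree(n)).tree_hierarchy for n in range(4, 16)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_matches_bruteforce_on_random_trees(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 13))
            v = symmetric_matrix(rng, n)
            tree = build_mst(v)
            got = mst_metrics(tree)
            expected = bruteforce_metrics(tree)
            for name in METRIC_NAMES:
                assert getattr(got, name) == pytest.approx(
                    getattr(expected, name), abs=1e-12
                ), name

    def test_metric_ranges(self, rng):
        for _ in range(10):
            tree = build_mst(symmetric_matrix(rng, 10))
            got = mst_metrics(tree)
            for name in METRIC_NAMES:
                assert 0.0 < getattr(got, name) <= 1.0, name

    def test_two_node_tree_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            mst_metrics(SpanningTree(2, ((0, 1, 0.5),)))


class TestSubjectProfile:
    def _adj_from_tree(self, tree, n):
        v = np.full((n, n), 0.1)
        np.fill_diagonal(v, 0.0)
        for i, j, _ in tree.edges:
            v[i, j] = v[j, i] = 0.9
        return AdjacencyMatrix(v, THETA, tuple(f"r{i}" for i in range(n)))

    def test_identical_epochs_reproduce_single_epoch(self, rng):
        adj = self._adj_from_tree(star_tree(10), 10)
        single = mst_metrics(build_mst(adj))
        prof = subject_mst_profile([adj] * 3)
        for name in METRIC_NAMES:
            assert getattr(prof, name) == pytest.approx(getattr(single, name))

    def test_star_and_path_epochs_average(self):
        a = self._adj_from_tree(star_tree(10), 10)
        b = self._adj_from_tree(path_tree(10), 10)
        prof = subject_mst_profile([a, b])
        star, path = mst_metrics(build_mst(a)), mst_metrics(build_mst(b))
        for name in METRIC_NAMES:
            assert getattr(prof, name) == pytest.approx(
                0.5 * (getattr(star, name) + getattr(path, name))
            )

    def test_epoch_order_irrelevant(self):
        a = self._adj_from_tree(star_tree(8), 8)
        b = self._adj_from_tree(path_tree(8), 8)
        p1 = subject_mst_profile([a, b])
        p2 = subject_mst_profile([b, a])
        assert p1 == p2
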