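import warnings

import networkx as nx
import numpy as np
import pytest

from npmap4.chemspace import (
    NeighborGraph,
    brute_force_knn,
    build_lsh_forest,
    export_graph,
    knn_graph,
    mst_kruskal,
    tree_layout,
)
from npmap4.fingerprint import similarity_matrix

from conftest import random_signatures


def prim_total_weight(edges, nodes):
    """Independent Prim's-algorithm oracle for spanning-forest weight."""
    import heapq

    adj = {n: [] for n in nodes}
    for u, v, w in edges:
        adj[u].append((w, v))
        adj[v].append((w, u))
    seen: set = set()
    total = 0.0
    for start in nodes:
        if start in seen:
            continue
        seen.add(start)
        heap = list(adj[start])
        heapq.heapify(heap)
        while heap:
            w, v = heapq.heappop(heap)
            if v in seen:
                continue
            seen.add(v)
            total += w
            for item in adj[v]:
                heapq.heappush(heap, item)
    return total


def random_graph(rng, n=50, p=0.3):
    nodes = [f"N{i:02d}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j], float(np.round(rng.random(), 6)))
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return NeighborGraph(nodes=nodes, edges=edges)


class TestLSHForest:
    def test_single_signature_is_its_own_neighbor(self):
        sigs = random_signatures(1, seed=0)
        forest = build_lsh_forest(["only"], sigs)
        assert forest.query(sigs[0], 1) == [("only", 0.0)]

    def test_duplicates_are_mutual_neighbors_at_distance_zero(self):
        sigs = np.repeat(random_signatures(1, seed=1), 2, axis=0)
        forest = build_lsh_forest(["a", "b"], sigs)
        assert forest.query(sigs[0], 1, exclude="a") == [("b", 0.0)]
        assert forest.query(sigs[1], 1, exclude="b") == [("a", 0.0)]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_lsh_forest([], np.empty((0, 1024), np.uint32))

    def test_reasonable_recall_on_clustered_signatures(self):
        # 12 clusters of near-duplicates: true neighbors are cluster mates
        rng = np.random.default_rng(2)
        bases = rng.integers(0, 2**31 - 1, size=(12, 1024), dtype=np.uint32)
        sigs = np.repeat(bases, 10, axis=0)
        for row in sigs:
            pos = rng.choice(1024, size=100, replace=False)
            row[pos] = rng.integers(0, 2**31 - 1, size=100, dtype=np.uint32)
        n, k = len(sigs), 8
        ids = [f"M{i:03d}" for i in range(n)]
        forest = build_lsh_forest(ids, sigs, seed=0)
        D = 1.0 - similarity_matrix(sigs, sigs)
        recalls = []
        for i in range(n):
            order = sorted((D[i, j], ids[j]) for j in range(n) if j != i)
            truth = {m for _, m in order[:k]}
            approx = {m for m, _ in forest.query(sigs[i], k, exclude=ids[i])}
            recalls.append(len(truth & approx) / k)
        assert np.mean(recalls) >= 0.8


class TestKnnGraphs:
    def test_three_equidistant_points_k2_complete(self):
        sigs = random_signatures(3, seed=3, n_shared=0)  # pairwise ~ disjoint
        g = brute_force_knn(["a", "b", "c"], sigs, 2)
        assert {(u, v) for u, v, _ in g.edges} == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_k_equal_n_minus_one_is_complete(self):
        n = 6
        sigs = random_signatures(n, seed=4)
        g = brute_force_knn([f"m{i}" for i in range(n)], sigs, n - 1)
        assert len(g.edges) == n * (n - 1) // 2

    def test_oversized_k_truncated_with_warning(self):
        sigs = random_signatures(3, seed=5)
        with pytest.warns(UserWarning, match="truncating"):
            g = brute_force_knn(["a", "b", "c"], sigs, 10)
        assert len(g.edges) == 3

    def test_brute_force_matches_independent_neighbor_computation(self):
        n, k = 25, 4
        ids = [f"m{i:02d}" for i in range(n)]
        sigs = random_signatures(n, seed=6, n_shared=600)
        g = brute_force_knn(ids, sigs, k)
        # independent path: boolean-mean distances + argsort per row
        D = 1.0 - (sigs[:, None, :] == sigs[None, :, :]).mean(axis=2)
        expected = set()
        for i in range(n):
            ranked = sorted((D[i, j], ids[j]) for j in range(n) if j != i)[:k]
            for d, other in ranked:
                expected.add(tuple(sorted((ids[i], other))))
        assert {(u, v) for u, v, _ in g.edges} == expected

    def test_lsh_graph_weights_are_exact_distances(self):
        n = 30
        ids = [f"m{i:02d}" for i in range(n)]
        sigs = random_signatures(n, seed=7, n_shared=600)
        forest = build_lsh_forest(ids, sigs, seed=0)
        g = knn_graph(forest, 5)
        idx = {m: i for i, m in enumerate(ids)}
        for u, v, w in g.edges:
            expected = 1.0 - np.mean(sigs[idx[u]] == sigs[idx[v]])
            assert w == pytest.approx(expected)

    def test_row_order_invariance_of_brute_force_graph(self):
        n = 20
        ids = [f"m{i:02d}" for i in range(n)]
        sigs = random_signatures(n, seed=8, n_shared=600)
        g1 = brute_force_knn(ids, sigs, 4)
        perm = np.random.default_rng(0).permutation(n)
        g2 = brute_force_knn([ids[i] for i in perm], sigs[perm], 4)
        assert {(u, v, round(w, 9)) for u, v, w in g1.edges} == {
            (u, v, round(w, 9)) for u, v, w in g2.edges
        }


class TestMST:
    def test_triangle_drops_heaviest_edge(self):
        g = NeighborGraph(
            nodes=["a", "b", "c"],
            edges=[("a", "b", 0.1), ("b", "c", 0.2), ("a", "c", 0.9)],
        )
        t = mst_kruskal(g)
        assert {(u, v) for u, v, _ in t.edges} == {("a", "b"), ("b", "c")}
        assert t.total_weight == pytest.approx(0.3)

    def test_tree_input_returned_unchanged(self):
        g = NeighborGraph(
            nodes=["a", "b", "c", "d"],
            edges=[("a", "b", 0.5), ("b", "c", 0.4), ("c", "d", 0.3)],
        )
        t = mst_kruskal(g)
        assert sorted(t.edges) == sorted(g.edges)

    def test_matches_prim_and_networkx_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            g = random_graph(rng)
            t = mst_kruskal(g)
            assert t.total_weight == pytest.approx(prim_total_weight(g.edges, g.nodes))
            nx_weight = nx.minimum_spanning_tree(g.to_networkx()).size(weight="weight")
            assert t.total_weight == pytest.approx(nx_weight)
            # structural invariants: acyclic subset, right edge count
            assert set((u, v) for u, v, _ in t.edges) <= set(
                tuple(sorted((u, v))) for u, v, _ in g.edges
            )
            tg = t.to_networkx()
            assert nx.is_forest(tg)
            assert len(t.edges) == len(g.nodes) - t.n_components

    def test_lsh_and_brute_force_agree_at_full_k(self):
        n = 18
        ids = [f"m{i:02d}" for i in range(n)]
        sigs = random_signatures(n, seed=9, n_shared=600)
        exact = mst_kruskal(brute_force_knn(ids, sigs, n - 1))
        forest = build_lsh_forest(ids, sigs, seed=0)
        approx = mst_kruskal(knn_graph(forest, n - 1))
        assert approx.total_weight == pytest.approx(exact.total_weight)

    def test_disconnected_graph_yields_forest(self):
        g = NeighborGraph(
            nodes=["a", "b", "c", "d"], edges=[("a", "b", 0.1), ("c", "d", 0.2)]
        )
        t = mst_kruskal(g)
        assert t.n_components == 2 and len(t.edges) == 2


class TestExportAndLayout:
    def tiny_tree(self):
        g = NeighborGraph(nodes=["a", "b"], edges=[("a", "b", 0.25)])
        return mst_kruskal(g)

    def test_two_node_tree_exports_one_edge_row(self, tmp_path):
        t = self.tiny_tree()
        ann = {"a": {"mw": 100.0}, "b": {"mw": 200.0}}
        edge_path, graphml_path = export_graph(t, tmp_path / "t", ann)
        lines = edge_path.read_text().splitlines()
        assert lines[0] == "source\ttarget\tweight" and len(lines) == 2
        back = nx.read_graphml(graphml_path)
        assert set(back.nodes) == {"a", "b"} and back.nodes["a"]["mw"] == 100.0

    def test_missing_annotation_lists_ids(self, tmp_path):
        t = self.tiny_tree()
        with pytest.raises(KeyError, match="b"):
            export_graph(t, tmp_path / "t", {"a": {}})

    def test_path_graph_layout_distinct_points(self):
        g = NeighborGraph(
            nodes=["a", "b", "c"], edges=[("a", "b", 0.1), ("b", "c", 0.1)]
        )
        coords = tree_layout(mst_kruskal(g), seed=0)
        assert len({(round(x, 6), round(y, 6)) for x, y in coords.values()}) == 3

    def test_layout_deterministic_under_seed(self):
        g = NeighborGraph(
            nodes=[f"n{i}" for i in range(7)],
            edges=[(f"n{i}", f"n{i + 1}", 0.1 * (i + 1)) for i in range(6)],
        )
        t = mst_kruskal(g)
        assert tree_layout(t, seed=3) == tree_layout(t, seed=3)

    def test_star_layout_separates_leaves_from_center(self):
        g = NeighborGraph(
            nodes=["hub", "x", "y", "z"],
            edges=[("hub", n, 0.2) for n in ("x", "y", "z")],
        )
        coords = tree_layout(mst_kruskal(g))
        hub = np.array(coords["hub"])
        for leaf in ("x", "y", "z"):
            assert np.linalg.norm(np.array(coords[leaf]) - hub) > 0.1
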