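"""Tree-map style chemical-space graphs over MinHash signatures.

Pipeline: an LSH forest indexes the signatures for approximate
nearest-neighbor retrieval; the per-molecule top-k neighbors form a weighted
kNN graph (weights are estimated Jaccard distances, recomputed exactly from
the signatures, not the index's internal approximation); Kruskal's algorithm
reduces the graph to a minimum spanning forest, which is exported as an edge
list / GraphML and can be drawn with a simple deterministic radial layout.

Defaults follow the reference configuration: 32 trees, k = 20 neighbors.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np

from .fingerprint import estimate_similarity, similarity_matrix

DEFAULT_N_TREES = 32
DEFAULT_K = 20

Edge = tuple[str, str, float]


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class NeighborGraph:
    """Weighted undirected kNN graph: nodes are molecule IDs, edge weights
    are estimated Jaccard distances in [0, 1]."""

    nodes: list[str]
    edges: list[Edge] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g


@dataclass
class SpanningTree:
    """Cycle-free minimum-weight subgraph of a NeighborGraph (a forest when
    the input graph is disconnected)."""

    nodes: list[str]
    edges: list[Edge] = field(default_factory=list)
    n_components: int = 1

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g


class LSHForest:
    """Prefix-tree ensemble over permuted signature slices.

    Each of the ``n_trees`` trees owns a distinct permuted slice of
    ``depth`` signature positions; inserted signatures are stored as sorted
    tuples of those positions. A query walks prefixes from the full depth
    downward, pooling candidates until enough are found, then ranks the pool
    by exact estimated similarity. Deterministic given the seed and the
    insertion order.
    """

    def __init__(self, n_trees: int = DEFAULT_N_TREES, depth: int | None = None, seed: int = 0):
        self.n_trees = n_trees
        self.seed = seed
        self.depth = depth
        self._ids: list[str] = []
        self._sigs: np.ndarray | None = None
        self._trees: list[list[tuple[tuple[int, ...], int]]] = []
        self._slices: list[np.ndarray] = []

    def fit(self, ids: Sequence[str], signatures: np.ndarray) -> "LSHForest":
        signatures = np.atleast_2d(np.asarray(signatures))
        if signatures.shape[0] == 0:
            raise ValueError("cannot build an LSH forest from zero signatures")
        if len(ids) != signatures.shape[0]:
            raise ValueError("ids / signatures length mismatch")
        dims = signatures.shape[1]
        depth = self.depth or max(4, dims // self.n_trees)
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(dims)
        self._slices = []
        for t in range(self.n_trees):
            lo = (t * depth) % dims
            take = perm[np.arange(lo, lo + depth) % dims]
            self._slices.append(take)
        self._ids = list(ids)
        self._sigs = signatures
        self._trees = []
        for take in self._slices:
            keyed = sorted(
                (tuple(int(v) for v in signatures[i, take]), i)
                for i in range(signatures.shape[0])
            )
            self._trees.append(keyed)
        return self

    def _candidates(self, signature: np.ndarray, min_pool: int) -> set[int]:
        pool: set[int] = set()
        if self._sigs is None:
            raise ValueError("forest is empty; call fit first")
        depth = len(self._slices[0])
        queries = [tuple(int(v) for v in signature[take]) for take in self._slices]
        for r in range(depth, 0, -1):
            for tree, q in zip(self._trees, queries):
                prefix = q[:r]
                i = bisect_left(tree, (prefix,))
                while i < len(tree) and tree[i][0][:r] == prefix:
                    pool.add(tree[i][1])
                    i += 1
            if len(pool) >= min_pool:
                break
        return pool

    def query(self, signature: np.ndarray, k: int, exclude: str | None = None) -> list[tuple[str, float]]:
        """Approximate top-k neighbors as (id, estimated Jaccard distance),
        sorted by (distance, id)."""
        n = len(self._ids)
        pool = self._candidates(signature, min_pool=min(n, max(4 * k, 64)))
        if len(pool) < min(n, k + 1):
            pool = set(range(n))  # degenerate prefix spread: fall back to scan
        scored = []
        for i in pool:
            mol_id = self._ids[i]
            if exclude is not None and mol_id == exclude:
                continue
            d = 1.0 - estimate_similarity(signature, self._sigs[i])
            scored.append((d, mol_id))
        scored.sort()
        return [(mol_id, d) for d, mol_id in scored[:k]]


def build_lsh_forest(
    ids: Sequence[str],
    signatures: np.ndarray,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> LSHForest:
    """Index signatures for approximate nearest-neighbor retrieval."""
    return LSHForest(n_trees=n_trees, seed=seed).fit(ids, signatures)


def _truncate_k(k: int, n: int) -> int:
    if k >= n:
        import warnings

        warnings.warn(f"k={k} >= n={n}; truncating to {n - 1}", stacklevel=3)
        return n - 1
    return k


def brute_force_knn(ids: Sequence[str], signatures: np.ndarray, k: int) -> NeighborGraph:
    """Exact top-k neighbor graph by full pairwise estimated distances.

    Ties broken by (distance, neighbor ID); edges symmetrized by union.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two signatures for a kNN graph")
    k = _truncate_k(k, n)
    dist = 1.0 - similarity_matrix(signatures, signatures)
    edges: dict[tuple[str, str], float] = {}
    for i in range(n):
        order = sorted((dist[i, j], ids[j], j) for j in range(n) if j != i)
        for d, _, j in order[:k]:
            edges[_edge_key(ids[i], ids[j])] = d
    return NeighborGraph(nodes=ids, edges=[(u, v, w) for (u, v), w in sorted(edges.items())])


def knn_graph(forest: LSHForest, k: int = DEFAULT_K) -> NeighborGraph:
    """Approximate kNN graph from an LSH forest, symmetrized by edge union;
    weights recomputed with the exact estimator."""
    ids = forest._ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two signatures for a kNN graph")
    k = _truncate_k(k, n)
    edges: dict[tuple[str, str], float] = {}
    for i, mol_id in enumerate(ids):
        for nb_id, d in forest.query(forest._sigs[i], k, exclude=mol_id):
            edges[_edge_key(mol_id, nb_id)] = d
    return NeighborGraph(nodes=list(ids), edges=[(u, v, w) for (u, v), w in sorted(edges.items())])


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y) -> bool:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return False
        self.parent[ry] = rx
        return True


def mst_kruskal(g: NeighborGraph, link_components: bool = False) -> SpanningTree:
    """Minimum spanning forest by Kruskal's algorithm.

    Edges are scanned in (weight, min ID, max ID) order for a deterministic
    result under ties. A disconnected graph yields a forest; with
    ``link_components`` the components are additionally joined through their
    closest inter-component pair so a single tree is returned (flagged edges
    keep their true weight).
    """
    if not g.nodes:
        raise ValueError("empty graph")
    uf = _UnionFind(g.nodes)
    chosen: list[Edge] = []
    for w, u, v in sorted((w, *_edge_key(u, v)) for u, v, w in g.edges):
        if uf.union(u, v):
            chosen.append((u, v, w))
    n_components = len(g.nodes) - len(chosen)
    if link_components and n_components > 1:
        # join remaining components greedily through their cheapest crossing
        # edge among all original edges; if none exist the components stay apart
        for w, u, v in sorted((w, *_edge_key(u, v)) for u, v, w in g.edges):
            if uf.union(u, v):
                chosen.append((u, v, w))
        n_components = len(g.nodes) - len(chosen)
    return SpanningTree(nodes=list(g.nodes), edges=chosen, n_components=n_components)


def export_graph(
    tree: SpanningTree,
    out_prefix: str | Path,
    annotations: Mapping[str, Mapping[str, object]] | None = None,
) -> tuple[Path, Path]:
    """Write the spanning tree as an edge-list TSV and a GraphML file.

    ``annotations`` maps node ID to a flat attribute dict (the color-code
    properties); every tree node must be covered or an error lists the
    missing IDs.
    """
    out_prefix = Path(out_prefix)
    if annotations is not None:
        missing = [n for n in tree.nodes if n not in annotations]
        if missing:
            raise KeyError(f"annotations missing for node IDs: {missing}")
    edge_path = out_prefix.with_suffix(".edges.tsv")
    with open(edge_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in tree.edges:
            fh.write(f"{u}\t{v}\t{w:.6f}\n")
    g = tree.to_networkx()
    if annotations is not None:
        for node in g.nodes:
            for key, value in annotations[node].items():
                g.nodes[node][key] = value if value is not None else ""
    graphml_path = out_prefix.with_suffix(".graphml")
    nx.write_graphml(g, graphml_path)
    return edge_path, graphml_path


def tree_layout(tree: SpanningTree, seed: int = 0) -> dict[str, tuple[float, float]]:
    """Deterministic 2-D radial layout of a spanning tree / forest.

    Per component: root at the highest-degree node (ties to the smallest
    ID), nodes placed on circles of radius = BFS depth, each subtree given
    an angular span proportional to its leaf count. The seed is accepted for
    API symmetry; the layout is deterministic regardless.
    """
    g = tree.to_networkx()
    coords: dict[str, tuple[float, float]] = {}
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    offset_x = 0.0
    for comp in components:
        sub = g.subgraph(comp)
        root = min(sorted(comp), key=lambda n: (-sub.degree[n], n))
        parent = {root: None}
        order = [root]
        for u in order:
            for v in sorted(sub.neighbors(u)):
                if v not in parent:
                    parent[v] = u
                    order.append(v)
        leaves: dict[str, int] = {}
        for u in reversed(order):
            kids = [v for v in sub.neighbors(u) if parent.get(v) == u]
            leaves[u] = max(1, sum(leaves[v] for v in kids))
        span: dict[str, tuple[float, float]] = {root: (0.0, 2.0 * math.pi)}
        depth = {root: 0}
        for u in order:
            lo, hi = span[u]
            kids = sorted(v for v in sub.neighbors(u) if parent.get(v) == u)
            total = sum(leaves[v] for v in kids) or 1
            cursor = lo
            for v in kids:
                width = (hi - lo) * leaves[v] / total
                span[v] = (cursor, cursor + width)
                depth[v] = depth[u] + 1
                cursor += width
        radius = max(depth.values()) or 1
        for u in order:
            lo, hi = span[u]
            theta = 0.5 * (lo + hi)
            r = depth[u]
            coords[u] = (offset_x + r * math.cos(theta), r * math.sin(theta))
        offset_x += 2.0 * radius + 2.0
    return coords


def write_layout(path: str | Path, coords: Mapping[str, tuple[float, float]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("compound_id\tx\ty\n")
        for mol_id in sorted(coords):
            x, y = coords[mol_id]
            fh.write(f"{mol_id}\t{x:.6f}\t{y:.6f}\n")
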