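"""gSpan frequent connected-subgraph mining with minimum DFS codes.

Each subject's thresholded binary network is a transaction: an
undirected labeled graph whose node labels are region names (uniform
edge label, since edges were binarized).  The miner enumerates every
connected subgraph pattern whose transaction support (number of graphs
containing at least one label-preserving subgraph-isomorphic embedding)
reaches a threshold, each pattern reported exactly once under its
canonical label — the lexicographically minimum depth-first-search (DFS)
code.  Candidate growth follows the rightmost-path extension rule and
candidates whose code is not minimal are pruned, so no pattern is
generated twice; anti-monotonicity of transaction support guarantees
pruning never loses a frequent pattern.

A DFS code is an ordered list of 5-tuples
``(i, j, label_i, edge_label, label_j)`` over discovery indices; the
first tuple has (i, j) = (0, 1) and each subsequent edge is either a
backward edge from the rightmost vertex to a vertex on the rightmost
path or a forward edge from a rightmost-path vertex to a new vertex.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .network import BinaryNetwork

__all__ = [
    "EDGE_LABEL",
    "LabeledGraph",
    "GraphDatabase",
    "FrequentSubgraph",
    "min_dfs_code",
    "is_min_code",
    "subgraph_support",
    "gspan_mine",
    "compare_frequent_patterns",
    "write_graph_database",
    "read_graph_database",
]

EDGE_LABEL = "_"

Code = tuple[tuple[int, int, str, str, str], ...]


@dataclass(frozen=True)
class LabeledGraph:
    """Undirected node-labeled graph with integer node ids 0..n-1.

    Node labels need not be unique; the miner never assumes uniqueness
    even though region names are unique in thresholded brain networks.
    """

    labels: tuple[str, ...]
    edges: frozenset[frozenset[int]]

    @staticmethod
    def build(labels: Sequence[str],
              edges: Iterable[tuple[int, int]]) -> "LabeledGraph":
        n = len(labels)
        es = set()
        for i, j in edges:
            if i == j:
                raise ValueError("self-loops are not allowed")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("edge endpoint out of range")
            es.add(frozenset((i, j)))
        return LabeledGraph(tuple(labels), frozenset(es))

    @staticmethod
    def from_network(net: BinaryNetwork) -> "LabeledGraph":
        return LabeledGraph.build(net.region_labels, net.edge_list())

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @functools.cached_property
    def adj(self) -> tuple[tuple[int, ...], ...]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for e in self.edges:
            i, j = tuple(e)
            nbrs[i].append(j)
            nbrs[j].append(i)
        return tuple(tuple(sorted(b)) for b in nbrs)

    def has_edge(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self.edges

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return False
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == self.n_nodes

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, lab in enumerate(self.labels):
            g.add_node(i, label=lab)
        for e in self.edges:
            i, j = tuple(e)
            g.add_edge(i, j)
        return g


@dataclass
class GraphDatabase:
    """A collection of transaction graphs for one session/group."""

    graphs: list[LabeledGraph]
    session: str = ""

    def __len__(self) -> int:
        return len(self.graphs)


@dataclass(frozen=True)
class FrequentSubgraph:
    """A mined pattern keyed by its minimum DFS code."""

    code: Code
    support: int
    edge_count: int
    params: tuple[int, int, int] | None = None  # (min_support, min_edges, max_edges)

    def graph(self) -> LabeledGraph:
        return _graph_of_code(self.code)

    def edge_labels(self) -> list[tuple[str, str]]:
        """Region-name pairs of the pattern's edges (sorted within pair)."""
        return [tuple(sorted((t[2], t[4]))) for t in self.code]


# ---------------------------------------------------------------------------
# DFS-code order
# ---------------------------------------------------------------------------

def _edge_lt(a, b) -> bool:
    """gSpan linear order on code edges: position rules first (forward /
    backward precedence along the rightmost path), labels break ties."""
    i1, j1, i2, j2 = a[0], a[1], b[0], b[1]
    fwd1, fwd2 = i1 < j1, i2 < j2
    if fwd1 and fwd2:
        if j1 != j2:
            return j1 < j2
        if i1 != i2:
            return i1 > i2
    elif not fwd1 and not fwd2:
        if i1 != i2:
            return i1 < i2
        if j1 != j2:
            return j1 < j2
    elif not fwd1:            # a backward, b forward
        return i1 < j2
    else:                     # a forward, b backward
        return j1 <= i2
    return a[2:] < b[2:]


_edge_key = functools.cmp_to_key(
    lambda a, b: -1 if _edge_lt(a, b) else (1 if _edge_lt(b, a) else 0))


def code_lt(c1: Code, c2: Code) -> bool:
    """Lexicographic DFS-code order; a proper prefix precedes its extensions."""
    for a, b in zip(c1, c2):
        if _edge_lt(a, b):
            return True
        if _edge_lt(b, a):
            return False
    return len(c1) < len(c2)


def _graph_of_code(code: Code) -> LabeledGraph:
    n = max(max(t[0], t[1]) for t in code) + 1
    labels: list[str | None] = [None] * n
    edges = []
    for i, j, li, _, lj in code:
        labels[i] = li
        labels[j] = lj
        edges.append((i, j))
    return LabeledGraph.build([str(l) for l in labels], edges)


def _rightmost_path(code: Code) -> list[int]:
    """Vertices on the rightmost path, rightmost vertex first, ending at 0."""
    rmv = max(max(t[0], t[1]) for t in code)
    path = [rmv]
    cur = rmv
    for t in reversed(code):
        i, j = t[0], t[1]
        if i < j and j == cur:
            path.append(i)
            cur = i
    return path


# ---------------------------------------------------------------------------
# minimum DFS code
# ---------------------------------------------------------------------------

def min_dfs_code(g: LabeledGraph) -> Code:
    """Canonical label: the lexicographically smallest DFS code over all
    depth-first traversals of ``g`` (connected, at least one edge).

    Maintains the full frontier of partial embeddings realizing the
    current minimal prefix, so the greedy tuple-by-tuple choice yields
    the global minimum.
    """
    if g.n_edges == 0:
        raise ValueError("graph has no edges")
    if not g.is_connected():
        raise ValueError("graph is not connected")
    m = g.n_edges

    # initial tuple: minimal (label_u, EDGE_LABEL, label_v) over directed edges
    best = None
    embs: list[tuple[int, ...]] = []
    for e in g.edges:
        for u, v in (tuple(e), tuple(e)[::-1]):
            key = (g.labels[u], EDGE_LABEL, g.labels[v])
            if best is None or key < best:
                best = key
                embs = [(u, v)]
            elif key == best:
                embs.append((u, v))
    code: list = [(0, 1) + best]

    while len(code) < m:
        rmpath = _rightmost_path(tuple(code))
        r = rmpath[0]
        nverts = max(max(t[0], t[1]) for t in code) + 1
        code_edges = {frozenset((t[0], t[1])) for t in code}
        best_t = None
        best_embs: list[tuple[int, ...]] = []
        for vmap in embs:
            mapped = set(vmap)
            # backward extensions from the rightmost vertex
            for v in rmpath[1:]:
                if frozenset((r, v)) in code_edges:
                    continue
                if g.has_edge(vmap[r], vmap[v]):
                    t = (r, v, g.labels[vmap[r]], EDGE_LABEL,
                         g.labels[vmap[v]])
                    if best_t is None or _edge_lt(t, best_t):
                        best_t, best_embs = t, [vmap]
                    elif t == best_t:
                        best_embs.append(vmap)
            # forward extensions from rightmost-path vertices
            for w in rmpath:
                gw = vmap[w]
                for u in g.adj[gw]:
                    if u in mapped:
                        continue
                    t = (w, nverts, g.labels[gw], EDGE_LABEL, g.labels[u])
                    if best_t is None or _edge_lt(t, best_t):
                        best_t, best_embs = t, [vmap + (u,)]
                    elif t == best_t:
                        best_embs.append(vmap + (u,))
        code.append(best_t)
        # deduplicate identical vertex maps (backward steps keep maps as-is)
        embs = list(dict.fromkeys(best_embs))
    return tuple(code)


def is_min_code(code: Code) -> bool:
    """True iff ``code`` is the minimum DFS code of the graph it encodes."""
    return min_dfs_code(_graph_of_code(code)) == tuple(code)


# ---------------------------------------------------------------------------
# support counting
# ---------------------------------------------------------------------------

def subgraph_support(pattern: LabeledGraph, db: GraphDatabase) -> int:
    """Transaction support: number of graphs in ``db`` containing at
    least one label-preserving subgraph-isomorphic embedding of
    ``pattern`` (multiple embeddings in one graph count once)."""
    if not pattern.is_connected():
        raise ValueError("pattern must be connected")
    pat_nx = pattern.to_networkx()
    node_match = nx.algorithms.isomorphism.categorical_node_match("label", None)
    count = 0
    for g in db.graphs:
        gm = nx.algorithms.isomorphism.GraphMatcher(
            g.to_networkx(), pat_nx, node_match=node_match)
        if gm.subgraph_is_monomorphic():
            count += 1
    return count


# ---------------------------------------------------------------------------
# mining
# ---------------------------------------------------------------------------

def default_min_support(n_transactions: int, fraction: float = 0.8) -> int:
    """ceil(fraction * |db|), at least 1."""
    import math
    return max(1, math.ceil(fraction * n_transactions))


def gspan_mine(db: GraphDatabase, min_support: int, min_edges: int = 2,
               max_edges: int = 6) -> list[FrequentSubgraph]:
    """Mine all frequent connected subgraph patterns of ``db``.

    Returns one :class:`FrequentSubgraph` per isomorphism class with
    transaction support >= ``min_support`` and edge count in
    [``min_edges``, ``max_edges``], sorted by minimum DFS code.
    """
    if len(db) == 0:
        raise ValueError("empty graph database")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if min_edges > max_edges or min_edges < 1:
        raise ValueError("require 1 <= min_edges <= max_edges")
    graphs = db.graphs
    params = (min_support, min_edges, max_edges)
    results: list[FrequentSubgraph] = []

    # frequent single-edge seeds, grouped by undirected label pair
    seeds: dict[tuple[str, str, str], list[tuple[int, int, int]]] = {}
    for gid, g in enumerate(graphs):
        for e in g.edges:
            u, v = tuple(e)
            la, lb = g.labels[u], g.labels[v]
            key = (min(la, lb), EDGE_LABEL, max(la, lb))
            seeds.setdefault(key, []).append((gid, u, v))

    def mine(code: list, embs: list[tuple[int, tuple[int, ...]]]) -> None:
        tcode = tuple(code)
        if not is_min_code(tcode):
            return
        support = len({gid for gid, _ in embs})
        if support < min_support:
            return
        if min_edges <= len(code) <= max_edges:
            results.append(FrequentSubgraph(tcode, support, len(code), params))
        if len(code) >= max_edges:
            return
        rmpath = _rightmost_path(tcode)
        r = rmpath[0]
        nverts = max(max(t[0], t[1]) for t in code) + 1
        code_edges = {frozenset((t[0], t[1])) for t in code}
        ext: dict[tuple, list[tuple[int, tuple[int, ...]]]] = {}
        for gid, vmap in embs:
            g = graphs[gid]
            mapped = set(vmap)
            for v in rmpath[1:]:
                if frozenset((r, v)) in code_edges:
                    continue
                if g.has_edge(vmap[r], vmap[v]):
                    t = (r, v, g.labels[vmap[r]], EDGE_LABEL,
                         g.labels[vmap[v]])
                    ext.setdefault(t, []).append((gid, vmap))
            for w in rmpath:
                gw = vmap[w]
                lw = g.labels[gw]
                for u in g.adj[gw]:
                    if u in mapped:
                        continue
                    t = (w, nverts, lw, EDGE_LABEL, g.labels[u])
                    ext.setdefault(t, []).append((gid, vmap + (u,)))
        for t in sorted(ext, key=_edge_key):
            nxt = ext[t]
            if len({gid for gid, _ in nxt}) >= min_support:
                mine(code + [t], nxt)

    for key in sorted(seeds):
        occ = seeds[key]
        if len({gid for gid, _, _ in occ}) < min_support:
            continue
        la, _, lb = key
        embs: list[tuple[int, tuple[int, ...]]] = []
        for gid, u, v in occ:
            g = graphs[gid]
            for a, b in ((u, v), (v, u)):
                if (g.labels[a], g.labels[b]) == (la, lb):
                    embs.append((gid, (a, b)))
        mine([(0, 1, la, EDGE_LABEL, lb)], embs)

    results.sort(key=lambda fs: [_edge_key(t) for t in fs.code])
    return results


def compare_frequent_patterns(pre: Sequence[FrequentSubgraph],
                              post: Sequence[FrequentSubgraph]
                              ) -> tuple[set[Code], set[Code], set[Code]]:
    """Set algebra on minimum-DFS-code keys.

    Returns ``(appeared, disappeared, persistent)`` where *appeared* are
    codes frequent post but not pre, *disappeared* the reverse, and
    *persistent* the intersection.  Both inputs must have been mined
    with identical support threshold and edge bounds.
    """
    params = {fs.params for fs in pre} | {fs.params for fs in post}
    params.discard(None)
    if len(params) > 1:
        raise ValueError(
            f"mismatched mining parameters between pattern lists: {params}")
    pre_keys = {fs.code for fs in pre}
    post_keys = {fs.code for fs in post}
    return (post_keys - pre_keys, pre_keys - post_keys,
            pre_keys & post_keys)


# ---------------------------------------------------------------------------
# gSpan exchange format
# ---------------------------------------------------------------------------

def write_graph_database(db: GraphDatabase, path) -> None:
    """One block per transaction: ``t # <id>``, then ``v <idx> <label>``
    lines, then ``e <i> <j> <label>`` lines."""
    with Path(path).open("w") as fh:
        for gid, g in enumerate(db.graphs):
            fh.write(f"t # {gid}\n")
            for i, lab in enumerate(g.labels):
                fh.write(f"v {i} {lab}\n")
            for e in sorted(tuple(sorted(e)) for e in g.edges):
                fh.write(f"e {e[0]} {e[1]} {EDGE_LABEL}\n")


def read_graph_database(path, session: str = "") -> GraphDatabase:
    graphs: list[LabeledGraph] = []
    labels: list[str] = []
    edges: list[tuple[int, int]] = []
    started = False

    def flush():
        if started:
            graphs.append(LabeledGraph.build(labels, edges))

    with Path(path).open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "t":
                flush()
                labels, edges = [], []
                started = True
            elif parts[0] == "v":
                idx = int(parts[1])
                if idx != len(labels):
                    raise ValueError("vertex indices must be consecutive")
                labels.append(parts[2])
            elif parts[0] == "e":
                edges.append((int(parts[1]), int(parts[2])))
    flush()
    return GraphDatabase(graphs, session)
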