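"""Shared fixtures and independent oracles.

The oracle implementations here deliberately avoid the library code
paths they check: shortest-path quantities come from hand-rolled BFS
layer counting (not igraph), and frequent-subgraph mining from explicit
edge-subset enumeration plus networkx isomorphism grouping (not the
gSpan traversal).
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from prepostnet.network import BinaryNetwork


# ---------------------------------------------------------------------------
# BFS oracles for nodal metrics
# ---------------------------------------------------------------------------

def bfs_dist_sigma(adj: np.ndarray, source: int):
    """Distances and shortest-path counts from ``source`` by explicit
    breadth-first layer expansion."""
    n = adj.shape[0]
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[source] = 0
    sigma[source] = 1
    frontier = [source]
    d = 0
    while frontier:
        nxt = []
        for u in frontier:
            for v in np.nonzero(adj[u])[0]:
                if dist[v] == np.inf:
                    dist[v] = d + 1
                    nxt.append(int(v))
        for v in set(nxt):
            sigma[v] = sum(sigma[u] for u in np.nonzero(adj[:, v])[0]
                           if dist[u] == d)
        frontier = sorted(set(nxt))
        d += 1
    return dist, sigma


def oracle_betweenness(adj: np.ndarray) -> np.ndarray:
    """Pair-by-pair shortest-path counting: for every pair s < t and
    candidate intermediary v, paths through v number
    sigma_sv * sigma_vt when d_sv + d_vt = d_st."""
    n = adj.shape[0]
    b = np.zeros(n)
    if n < 3:
        return b
    dist = np.empty((n, n))
    sigma = np.empty((n, n))
    for s in range(n):
        dist[s], sigma[s] = bfs_dist_sigma(adj, s)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]):
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    b[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return b / ((n - 1) * (n - 2) / 2.0)


def oracle_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    e = np.zeros(n)
    for s in range(n):
        dist, _ = bfs_dist_sigma(adj, s)
        with np.errstate(divide="ignore"):
            inv = 1.0 / dist
        inv[s] = 0.0
        inv[~np.isfinite(inv)] = 0.0
        e[s] = inv.sum() / (n - 1)
    return e


def as_network(adj: np.ndarray, sparsity: float = 0.5) -> BinaryNetwork:
    adj = np.asarray(adj, dtype=np.uint8)
    labels = tuple(f"n{i:02d}" for i in range(adj.shape[0]))
    return BinaryNetwork(adj, sparsity, labels)


# ---------------------------------------------------------------------------
# brute-force frequent-subgraph oracle
# ---------------------------------------------------------------------------

_NODE_MATCH = nx.algorithms.isomorphism.categorical_node_match("label", None)


def _labeled_nx(labels, edges) -> nx.Graph:
    g = nx.Graph()
    for i, lab in enumerate(labels):
        g.add_node(i, label=lab)
    g.add_edges_from(edges)
    return g


def oracle_mine(graphs, min_support: int, min_edges: int, max_edges: int):
    """Enumerate every connected edge subset of every transaction, group
    subgraphs by labeled isomorphism, and keep classes whose
    transaction support reaches the threshold.

    Returns a list of ``(nx.Graph pattern, support)``.
    """
    classes: list[list] = []   # [nx graph, invariant, set of gids]
    for gid, (labels, edges) in enumerate(graphs):
        edges = sorted(tuple(sorted(e)) for e in edges)
        for k in range(min_edges, max_edges + 1):
            for sub in itertools.combinations(edges, k):
                nodes = sorted({v for e in sub for v in e})
                sub_labels = [labels[v] for v in nodes]
                remap = {v: i for i, v in enumerate(nodes)}
                sub_edges = [(remap[a], remap[b]) for a, b in sub]
                sg = _labeled_nx(sub_labels, sub_edges)
                if not nx.is_connected(sg):
                    continue
                inv = (len(nodes), k, tuple(sorted(sub_labels)),
                       tuple(sorted((d, sg.nodes[v]["label"])
                                    for v, d in sg.degree())))
                for cls in classes:
                    if cls[1] == inv and nx.is_isomorphic(
                            cls[0], sg, node_match=_NODE_MATCH):
                        cls[2].add(gid)
                        break
                else:
                    classes.append([sg, inv, {gid}])
    return [(c[0], len(c[2])) for c in classes if len(c[2]) >= min_support]


def random_labeled_graph(rng, max_nodes=6, max_edges=8, alphabet="ABCD"):
    """(labels, edges) pair for a random transaction graph."""
    n = int(rng.integers(2, max_nodes + 1))
    labels = [alphabet[int(rng.integers(len(alphabet)))] for _ in range(n)]
    possible = list(itertools.combinations(range(n), 2))
    m = int(rng.integers(1, min(max_edges, len(possible)) + 1))
    idx = rng.choice(len(possible), size=m, replace=False)
    return labels, [possible[i] for i in idx]


@pytest.fixture(scope="session")
def atlas_connected():
    """All non-isomorphic connected graphs on 2..7 nodes (Graph Atlas)."""
    graphs = []
    for g in nx.graph_atlas_g()[1:]:
        if g.number_of_nodes() >= 2 and g.number_of_edges() >= 1 \
                and nx.is_connected(g):
            graphs.append(nx.to_numpy_array(g, dtype=np.uint8))
    return graphs


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared across tests."""
    from prepostnet.cohort import CohortConfig, generate_cohort
    cfg = CohortConfig(n_subjects=6, n_volumes=120, seed=42)
    ts, motions, behavior = generate_cohort(cfg)
    return cfg, ts, motions, behavior
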