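"""Nodal graph metrics, AUC summaries and hub detection.

Three per-node metrics on each binary network: degree k_i, betweenness
centrality b_i (normalized by (N-1)(N-2)/2) and nodal efficiency e_i
(mean inverse shortest-path length to all other nodes, unreachable
nodes contributing 0).  Metrics are computed at every sparsity level of
the threshold space; each (node, metric) curve is summarized by its
trapezoidal area under the curve (AUC) over the S axis, the quantity
entering group statistics.  Hubs are nodes whose group-mean degree lies
at least one standard deviation above the across-node mean.

Shortest-path computations are delegated to igraph's C routines; tests
verify them against exhaustive breadth-first-search oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .network import BinaryNetwork, ConnectivityMatrix, \
    SparsityThresholdSpace, threshold_by_sparsity

__all__ = [
    "METRICS",
    "MetricCurve",
    "HubSet",
    "nodal_degree",
    "betweenness_centrality",
    "nodal_efficiency",
    "all_nodal_metrics",
    "metric_curves",
    "metric_curve_matrices",
    "auc",
    "auc_table",
    "detect_hubs",
]

METRICS = ("degree", "betweenness", "efficiency")


@dataclass
class MetricCurve:
    """One node's metric values across the threshold space."""

    metric: str
    node: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class HubSet:
    """Regions whose group-mean degree is >= mean + 1 SD across nodes."""

    session: str
    hubs: tuple[str, ...]
    criterion: str = "mean + 1 SD of group-mean degree (population SD)"


def _graph(net: BinaryNetwork) -> ig.Graph:
    edges = net.edge_list()
    return ig.Graph(n=net.n_regions, edges=edges, directed=False)


def nodal_degree(net: BinaryNetwork) -> np.ndarray:
    """k_i: number of edges incident to each node."""
    return net.adjacency.sum(axis=0).astype(float)


def betweenness_centrality(net: BinaryNetwork) -> np.ndarray:
    """b_i: fraction of all-pairs shortest paths through node i.

    Sum over unordered pairs s < t (s, t != i) of sigma_st(i)/sigma_st,
    normalized by (N-1)(N-2)/2; pairs in different components contribute
    0.  For N < 3 the vector is all zeros by convention.
    """
    n = net.n_regions
    if n < 3:
        return np.zeros(n)
    raw = np.asarray(_graph(net).betweenness(directed=False), dtype=float)
    return raw / ((n - 1) * (n - 2) / 2.0)


def nodal_efficiency(net: BinaryNetwork) -> np.ndarray:
    """e_i = mean over j != i of 1/d_ij; unreachable pairs contribute 0."""
    n = net.n_regions
    d = np.asarray(_graph(net).distances(), dtype=float)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def all_nodal_metrics(net: BinaryNetwork) -> dict[str, np.ndarray]:
    """All three metrics, sharing one graph construction."""
    n = net.n_regions
    g = _graph(net)
    if n < 3:
        b = np.zeros(n)
    else:
        b = np.asarray(g.betweenness(directed=False), dtype=float) \
            / ((n - 1) * (n - 2) / 2.0)
    d = np.asarray(g.distances(), dtype=float)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return {
        "degree": nodal_degree(net),
        "betweenness": b,
        "efficiency": inv.sum(axis=1) / (n - 1),
    }


def metric_curve_matrices(c: ConnectivityMatrix,
                          space: SparsityThresholdSpace,
                          use_absolute: bool = True
                          ) -> dict[str, np.ndarray]:
    """All metric curves at once: metric -> (|space| x N) array.

    Equivalent to thresholding at every S and computing each metric,
    but ranks the edge pairs once per matrix (the nested edge sets
    across S share a single ordering).
    """
    from .network import target_edge_count
    n = c.n_regions
    iu, ju = np.triu_indices(n, k=1)
    weights = c.values[iu, ju]
    if use_absolute:
        weights = np.abs(weights)
    order = np.lexsort((ju, iu, -weights))
    out = {m: np.empty((len(space), n)) for m in METRICS}
    for row, s in enumerate(space):
        k = target_edge_count(n, s)
        if k == 0:
            raise ValueError(f"sparsity {s} retains zero edges for N={n}")
        sel = order[:k]
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[iu[sel], ju[sel]] = 1
        adj |= adj.T
        net = BinaryNetwork(adj, s, c.region_labels)
        for m, vec in all_nodal_metrics(net).items():
            out[m][row] = vec
    return out


def metric_curves(c: ConnectivityMatrix, space: SparsityThresholdSpace,
                  use_absolute: bool = True) -> list[MetricCurve]:
    """3 x N curves of length |space| (threshold, then compute each metric)."""
    mats = metric_curve_matrices(c, space, use_absolute=use_absolute)
    return [MetricCurve(m, c.region_labels[i], mats[m][:, i])
            for m in METRICS for i in range(c.n_regions)]


def auc(curve, space: SparsityThresholdSpace) -> float:
    """Trapezoidal area under a metric curve over the S axis."""
    values = curve.values if isinstance(curve, MetricCurve) else \
        np.asarray(curve, dtype=float)
    if len(space) < 2:
        raise ValueError("AUC needs at least two threshold levels")
    if len(values) != len(space):
        raise ValueError("curve length must match the threshold space")
    return float(np.trapezoid(values, np.asarray(space.values)))


def auc_table(curve_mats: dict[str, np.ndarray],
              space: SparsityThresholdSpace,
              region_labels, subject: str, session: str) -> pd.DataFrame:
    """Tidy AUC rows: (subject, session, metric, node, auc)."""
    s = np.asarray(space.values)
    rows = []
    for m in METRICS:
        a = np.trapezoid(curve_mats[m], s, axis=0)
        for i, label in enumerate(region_labels):
            rows.append({"subject": subject, "session": session,
                         "metric": m, "node": label, "auc": float(a[i])})
    return pd.DataFrame(rows)


def detect_hubs(group_mean_degree: np.ndarray, region_labels,
                session: str = "", ddof: int = 0) -> HubSet:
    """Hub rule: value >= mean + 1 SD (population SD by default),
    inclusive at the boundary; zero variance yields no hubs."""
    v = np.asarray(group_mean_degree, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 nodes")
    sd = v.std(ddof=ddof)
    if sd == 0:
        return HubSet(session, ())
    cut = v.mean() + sd
    hubs = tuple(region_labels[i] for i in np.nonzero(v >= cut - 1e-12)[0])
    return HubSet(session, hubs)
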