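"""Correlation networks and sparsity thresholding.

ROI time series -> full Pearson correlation matrix -> binary undirected
networks across a sparsity threshold space.  Sparsity S is the fraction
of retained edges over all N(N-1)/2 possible pairs; at each S exactly
k = round(S * N(N-1)/2) edges are kept, ranked by correlation magnitude
(configurable to signed ranking), with deterministic lexicographic
tie-breaking so that every subject's network has identical edge count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .cohort import ROITimeSeriesSet

__all__ = [
    "ConnectivityMatrix",
    "SparsityThresholdSpace",
    "BinaryNetwork",
    "regress_confounds",
    "correlation_matrix",
    "threshold_by_sparsity",
    "build_threshold_space",
    "write_connectivity",
    "read_connectivity",
    "write_network",
]


@dataclass
class ConnectivityMatrix:
    """Full N x N Pearson correlation matrix with region labels."""

    values: np.ndarray
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.region_labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match region_labels")
        if not np.isfinite(v).all():
            raise ValueError("correlation matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 1.0)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


@dataclass(frozen=True)
class SparsityThresholdSpace:
    """Inclusive arithmetic sequence of sparsity levels.

    The default analysis space runs from 5% to 40% in 1% steps
    (36 levels).
    """

    s_min: float
    s_max: float
    step: float
    values: tuple[float, ...] = field(default=(), compare=False)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    @property
    def width(self) -> float:
        return self.s_max - self.s_min


def build_threshold_space(s_min: float = 0.05, s_max: float = 0.40,
                          step: float = 0.01) -> SparsityThresholdSpace:
    """Build the sparsity threshold space ``s_min, s_min+step, ..., s_max``."""
    if not 0.0 < s_min < s_max <= 1.0:
        raise ValueError("require 0 < s_min < s_max <= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    span = (s_max - s_min) / step
    n_steps = round(span)
    if n_steps < 1 or abs(span - n_steps) > 1e-9 * max(1.0, span):
        raise ValueError("(s_max - s_min) must be an integer multiple of step")
    values = tuple(float(s_min + step * i) for i in range(n_steps + 1))
    return SparsityThresholdSpace(s_min, s_max, step, values)


@dataclass
class BinaryNetwork:
    """Sparsity-thresholded binary undirected graph."""

    adjacency: np.ndarray
    sparsity: float
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = len(self.region_labels)
        if a.shape != (n, n):
            raise ValueError("adjacency shape must match region_labels")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def regress_confounds(ts: ROITimeSeriesSet,
                      confounds: np.ndarray | None) -> ROITimeSeriesSet:
    """Replace each region's series by its least-squares residual against
    an intercept plus the confound columns (e.g. the six motion
    parameters, CSF and white-matter signals).

    With no confounds this reduces to mean-centering.  A rank-deficient
    design fails, naming the collinear columns.
    """
    t = ts.n_timepoints
    if confounds is None:
        confounds = np.empty((t, 0))
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != t:
        raise ValueError("confound rows must match the series length")
    design = np.hstack([np.ones((t, 1)), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValueError(
            "confound design matrix is rank-deficient; collinear columns "
            f"(0 = intercept): {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ beta
    return ROITimeSeriesSet(ts.subject_id, ts.session, resid,
                            ts.region_labels)


def _collinear_columns(design: np.ndarray) -> list[int]:
    """Columns whose removal restores full rank (diagnostic only)."""
    full = np.linalg.matrix_rank(design)
    bad = []
    for j in range(design.shape[1]):
        rest = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(rest) == full:
            bad.append(j)
    return bad


def correlation_matrix(ts: ROITimeSeriesSet) -> ConnectivityMatrix:
    """Region-wise Pearson correlation matrix of the series columns."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlations")
    sd = ts.data.std(axis=0)
    const = np.nonzero(sd == 0)[0]
    if const.size:
        names = [ts.region_labels[i] for i in const]
        raise ValueError(f"constant-valued region series: {names}")
    values = np.corrcoef(ts.data, rowvar=False)
    values = np.clip(values, -1.0, 1.0)
    return ConnectivityMatrix(values, ts.region_labels)


def target_edge_count(n_regions: int, sparsity: float) -> int:
    """k = round(S * N(N-1)/2), half away from zero."""
    possible = n_regions * (n_regions - 1) // 2
    return int(np.floor(sparsity * possible + 0.5))


def threshold_by_sparsity(c: ConnectivityMatrix, sparsity: float,
                          use_absolute: bool = True) -> BinaryNetwork:
    """Binarize a correlation matrix at one sparsity level.

    Retains exactly ``round(S * N(N-1)/2)`` edges, the largest
    off-diagonal pairs by |r| (or by signed r with
    ``use_absolute=False``); ties are broken by (i, j) lexicographic
    order, ascending, so that the edge set at sparsity s nests inside
    the edge set at any s' > s.
    """
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must lie in (0, 1]")
    n = c.n_regions
    k = target_edge_count(n, sparsity)
    if k == 0:
        raise ValueError(
            f"sparsity {sparsity} retains zero edges for N={n}")
    iu, ju = np.triu_indices(n, k=1)
    weights = c.values[iu, ju]
    if use_absolute:
        weights = np.abs(weights)
    # stable sort on (-weight, i, j): lexsort uses the last key as primary
    order = np.lexsort((ju, iu, -weights))
    sel = order[:k]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[sel], ju[sel]] = 1
    adj |= adj.T
    return BinaryNetwork(adj, sparsity, c.region_labels)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_connectivity(c: ConnectivityMatrix, path) -> None:
    """Square CSV with region labels as header and row index."""
    labels = list(c.region_labels)
    pd.DataFrame(c.values, index=labels, columns=labels).to_csv(path)


def read_connectivity(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(df.to_numpy(), tuple(df.columns))


def write_network(net: BinaryNetwork, edge_path, sidecar_path=None) -> None:
    """Edge-list text (label_i, label_j per line, i < j) plus a JSON
    sidecar recording sparsity and N."""
    edge_path = Path(edge_path)
    with edge_path.open("w") as fh:
        for i, j in net.edge_list():
            fh.write(f"{net.region_labels[i]}\t{net.region_labels[j]}\n")
    sidecar = Path(sidecar_path) if sidecar_path is not None \
        else edge_path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"sparsity": net.sparsity, "n_regions": net.n_regions,
         "n_edges": net.n_edges}, indent=2) + "\n")
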