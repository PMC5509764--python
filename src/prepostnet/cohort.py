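"""Synthetic pre/post resting-state cohorts.

Generates ROI time series, motion traces, demographics and behavioral
scores with the statistical structure a paired (pre vs. post
intervention) functional-connectivity study assumes:

* per subject and session, a ``T x N`` multivariate-normal ROI series
  drawn from a modular base correlation matrix;
* a session effect injected on the post-session correlation structure
  for a chosen set of regions ("effect nodes");
* behavioral score changes linearly coupled to each subject's realized
  connectivity change, plus Gaussian noise;
* six-parameter motion traces, with a controllable fraction of subjects
  whose post-session translations exceed the exclusion threshold.

Also implements the subject-level QC steps that act on ROI-level data:
discarding initial volumes and motion-based subject exclusion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AAL90_LABELS",
    "CohortConfig",
    "ROITimeSeriesSet",
    "MotionTrace",
    "BehavioralTable",
    "CovarianceRepairError",
    "base_correlation",
    "inject_effect",
    "nearest_psd_correlation",
    "generate_cohort",
    "discard_initial_volumes",
    "apply_motion_exclusion",
    "write_timeseries",
    "read_timeseries",
    "write_motion",
    "read_motion",
]

# AAL parcellation, 90 cerebral regions (45 per hemisphere), conventional
# abbreviations; left/right interleaved in atlas order.
_AAL45 = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING", "SOG",
    "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG", "PCUN", "PCL",
    "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup", "MTG", "TPOmid",
    "ITG",
]
AAL90_LABELS: tuple[str, ...] = tuple(
    f"{name}.{hemi}" for name in _AAL45 for hemi in ("L", "R")
)

MOTION_THRESHOLD_MM = 2.5  # max |translation| above which a subject is dropped

SESSIONS = ("pre", "post")

#: behavioral scales carried by the generator: two full-scale quotients
#: (intelligence, memory) and four subtests entering the correlation stage.
DEFAULT_SCALES: dict[str, tuple[float, float]] = {
    # scale -> (baseline mean, baseline SD), WAIS-RC / WMS conventions
    "FIQ": (120.0, 9.0),
    "MQ": (120.0, 10.0),
    "Associate": (12.0, 3.0),
    "Visual reproduction": (12.0, 3.0),
    "Block design": (12.0, 3.0),
    "Picture completion": (12.0, 3.0),
}


class CovarianceRepairError(ValueError):
    """Raised when a target covariance cannot be repaired to a valid
    positive-semidefinite correlation matrix."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design constants for a synthetic pre/post cohort.

    Defaults mirror the emulated design: 30 subjects, 90 AAL regions,
    212 acquired volumes of which the first 10 are discarded, a +0.3
    correlation increment injected between two cross-module effect nodes
    in the post session, and roughly one in ten subjects exceeding the
    2.5 mm translation limit.
    """

    n_subjects: int = 30
    n_regions: int = 90
    n_volumes: int = 212
    n_discard: int = 10
    effect_nodes: tuple[int, ...] = (0, 18)
    effect_delta: float = 0.3
    behavior_beta: float = 300.0
    behavior_noise_sd: float = 5.0
    motion_exceed_fraction: float = 0.1
    seed: int = 0
    # base-correlation shape (block-modular with within-module distance decay;
    # set within_gain=0 for a flat within/between block structure)
    n_modules: int = 5
    within_base: float = 0.3
    within_gain: float = 0.35
    within_decay: float = 0.5
    between_r: float = 0.1

    def __post_init__(self) -> None:
        if self.n_volumes <= self.n_discard:
            raise ValueError("n_volumes must exceed n_discard")
        if not 0.0 <= self.motion_exceed_fraction <= 1.0:
            raise ValueError("motion_exceed_fraction must lie in [0, 1]")
        if any(not 0 <= i < self.n_regions for i in self.effect_nodes):
            raise ValueError("effect_nodes must be region indices in "
                             f"[0, {self.n_regions})")
        if self.n_subjects < 1 or self.n_regions < 2:
            raise ValueError("need at least 1 subject and 2 regions")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ROITimeSeriesSet:
    """One subject-session matrix of region signals (T timepoints x N regions)."""

    subject_id: str
    session: str
    data: np.ndarray
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (T x N)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.data.shape[1] != len(self.region_labels):
            raise ValueError("column count must match region_labels")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters for one subject-session."""

    subject_id: str
    session: str
    translations: np.ndarray  # T x 3, millimetres
    rotations: np.ndarray     # T x 3, radians

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.translations.shape != self.rotations.shape or \
                self.translations.ndim != 2 or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be T x 3")

    @property
    def max_abs_translation(self) -> float:
        return float(np.max(np.abs(self.translations)))

    def as_matrix(self) -> np.ndarray:
        """T x 6 confound matrix (3 translations then 3 rotations)."""
        return np.hstack([self.translations, self.rotations])


@dataclass
class BehavioralTable:
    """Tidy behavioral scores plus demographics.

    ``scores``: one row per (subject_id, group, session, scale) with a
    finite ``score``; ``demographics``: one row per subject with age
    (years) and sex ({M, F}).
    """

    scores: pd.DataFrame
    demographics: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "session", "scale", "score"}
        if not required.issubset(self.scores.columns):
            raise ValueError(f"scores table needs columns {sorted(required)}")
        dup = self.scores.duplicated(subset=["subject_id", "session", "scale"])
        if dup.any():
            raise ValueError("duplicate (subject, session, scale) rows")
        if not np.isfinite(self.scores["score"]).all():
            raise ValueError("scores must be finite")

    def wide(self, scale: str) -> pd.DataFrame:
        """Per-subject pre/post columns for one scale."""
        sub = self.scores[self.scores["scale"] == scale]
        return sub.pivot(index="subject_id", columns="session", values="score")


# ---------------------------------------------------------------------------
# base correlation structure and effect injection
# ---------------------------------------------------------------------------

def base_correlation(config: CohortConfig) -> np.ndarray:
    """Modular base correlation matrix shared by all subjects.

    Regions are split into ``n_modules`` contiguous blocks.  Within a
    module the correlation decays with index distance d as
    ``within_base + within_gain * exp(-(d-1)/within_decay)`` so that a
    connectome-like gradient of strong, reliable edges down to weak ones
    exists; between modules the correlation is flat ``between_r``.
    """
    n = config.n_regions
    module = np.arange(n) * config.n_modules // n  # contiguous, near-equal
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    within = config.within_base + config.within_gain * np.exp(
        -(dist - 1) / config.within_decay
    )
    corr = np.where(module[:, None] == module[None, :], within, config.between_r)
    np.fill_diagonal(corr, 1.0)
    return nearest_psd_correlation(corr)


def inject_effect(corr: np.ndarray, effect_nodes: Sequence[int],
                  effect_delta: float) -> np.ndarray:
    """Increment the correlations between every pair of effect nodes.

    The increment is applied on the correlation scale, clipped to
    [-0.99, 0.99], and the matrix is then repaired to the nearest valid
    positive-semidefinite correlation matrix.
    """
    out = corr.copy()
    nodes = list(effect_nodes)
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            i, j = nodes[a], nodes[b]
            v = np.clip(out[i, j] + effect_delta, -0.99, 0.99)
            out[i, j] = out[j, i] = v
    return nearest_psd_correlation(out)


def nearest_psd_correlation(mat: np.ndarray, tol: float = 1e-10,
                            max_iter: int = 10) -> np.ndarray:
    """Repair a symmetric matrix to a positive-semidefinite correlation
    matrix by eigenvalue clipping at 0 and rescaling the diagonal to 1.

    Raises :class:`CovarianceRepairError` if the repair fails to converge
    (e.g. a diagonal entry collapses to zero).
    """
    m = np.array((mat + mat.T) / 2.0, dtype=float)
    for _ in range(max_iter):
        w, q = np.linalg.eigh(m)
        if w[0] >= -tol:
            break
        m = (q * np.clip(w, 0.0, None)) @ q.T
        d = np.diag(m).copy()
        if np.any(d <= tol):
            raise CovarianceRepairError(
                "diagonal entry vanished during PSD repair; the requested "
                "correlation structure is not realizable")
        scale = 1.0 / np.sqrt(d)
        m = m * np.outer(scale, scale)
    else:
        raise CovarianceRepairError("PSD repair did not converge")
    np.fill_diagonal(m, 1.0)
    return m


def _factor(corr: np.ndarray) -> np.ndarray:
    """Square-root factor F with F @ F.T = corr (PSD, possibly singular)."""
    w, q = np.linalg.eigh(corr)
    return q * np.sqrt(np.clip(w, 0.0, None))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig):
    """Generate one synthetic cohort.

    Returns ``(timeseries, motions, behavior)`` where *timeseries* is a
    list of :class:`ROITimeSeriesSet` (two sessions per subject),
    *motions* a matching list of :class:`MotionTrace`, and *behavior* a
    :class:`BehavioralTable`.  Identical configs (including the seed)
    give identical output.
    """
    rng = np.random.default_rng(config.seed)
    labels = _region_labels(config.n_regions)

    corr_pre = base_correlation(config)
    corr_post = inject_effect(corr_pre, config.effect_nodes,
                              config.effect_delta) \
        if config.effect_delta != 0 and len(config.effect_nodes) >= 2 \
        else corr_pre
    factors = {"pre": _factor(corr_pre), "post": _factor(corr_post)}

    n_exceed = int(round(config.motion_exceed_fraction * config.n_subjects))
    exceed_ids = set(range(n_exceed))  # deterministic assignment

    nodes = list(config.effect_nodes)

    timeseries: list[ROITimeSeriesSet] = []
    motions: list[MotionTrace] = []
    realized_change = np.zeros(config.n_subjects)

    for s in range(config.n_subjects):
        sid = f"sub-{s + 1:03d}"
        session_auc = {}
        for session in SESSIONS:
            z = rng.standard_normal((config.n_volumes, config.n_regions))
            data = z @ factors[session].T
            timeseries.append(ROITimeSeriesSet(sid, session, data, labels))
            motions.append(_motion_trace(rng, sid, session, config.n_volumes,
                                         spike=(session == "post"
                                                and s in exceed_ids)))
            kept = data[config.n_discard:]
            session_auc[session] = (
                _betweenness_auc(kept, nodes).mean() if nodes else 0.0)
        realized_change[s] = session_auc["post"] - session_auc["pre"]

    behavior = _behavioral_table(rng, config, realized_change)
    return timeseries, motions, behavior


#: coarse grid over the canonical 5-40% sparsity space used by the
#: generator's behavioral coupling (a subsample of the analysis space;
#: the realized metric change only has to track the subject, not match
#: the analysis AUC exactly)
_COUPLING_GRID = np.arange(0.05, 0.401, 0.05)


def _betweenness_auc(data: np.ndarray, nodes: list[int]) -> np.ndarray:
    """Realized betweenness-centrality AUC of ``nodes`` over the coarse
    sparsity grid, from raw series ``data`` (T x N); mirrors the analysis
    thresholding (|r| ranking, lexicographic tie-break)."""
    import igraph as ig
    c = np.abs(np.corrcoef(data, rowvar=False))
    n = c.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, -c[iu, ju]))
    norm = (n - 1) * (n - 2) / 2.0
    curves = np.empty((len(_COUPLING_GRID), len(nodes)))
    for row, s in enumerate(_COUPLING_GRID):
        k = int(np.floor(s * iu.size + 0.5))
        sel = order[:k]
        g = ig.Graph(n=n, edges=list(zip(iu[sel].tolist(),
                                         ju[sel].tolist())))
        b = np.asarray(g.betweenness(directed=False), dtype=float) / norm
        curves[row] = b[nodes]
    return np.trapezoid(curves, _COUPLING_GRID, axis=0)


def _region_labels(n: int) -> tuple[str, ...]:
    if n == len(AAL90_LABELS):
        return AAL90_LABELS
    return tuple(f"R{i:03d}" for i in range(n))


def _motion_trace(rng: np.random.Generator, sid: str, session: str,
                  n_volumes: int, spike: bool) -> MotionTrace:
    # slow drift, well inside the threshold unless a spike is injected
    trans = np.cumsum(rng.normal(0.0, 0.02, size=(n_volumes, 3)), axis=0)
    trans = np.clip(trans, -2.0, 2.0)
    rot = np.cumsum(rng.normal(0.0, 0.0004, size=(n_volumes, 3)), axis=0)
    if spike:
        t0 = int(rng.integers(n_volumes // 2, n_volumes))
        axis = int(rng.integers(3))
        trans[t0:, axis] += 3.0  # guarantees max |translation| > 2.5 mm
    return MotionTrace(sid, session, trans, rot)


def _behavioral_table(rng: np.random.Generator, config: CohortConfig,
                      realized_change: np.ndarray) -> BehavioralTable:
    rows = []
    demo = []
    # treated group: paired pre/post, change coupled to connectivity change
    for s in range(config.n_subjects):
        sid = f"sub-{s + 1:03d}"
        age = float(np.clip(rng.normal(34.5, 10.6), 20, 55))
        sex = "M" if rng.random() < 0.2 else "F"
        demo.append({"subject_id": sid, "age": age, "sex": sex})
        for scale, (mu, sd) in DEFAULT_SCALES.items():
            pre = rng.normal(mu, sd)
            change = (config.behavior_beta * realized_change[s]
                      + rng.normal(0.0, config.behavior_noise_sd))
            rows.append({"subject_id": sid, "group": "CG", "session": "pre",
                         "scale": scale, "score": pre})
            rows.append({"subject_id": sid, "group": "CG", "session": "post",
                         "scale": scale, "score": pre + change})
    # untreated controls: test-retest only, no coupled change
    n_controls = max(2, int(round(config.n_subjects * 0.7)))
    for s in range(n_controls):
        sid = f"ctl-{s + 1:03d}"
        age = float(np.clip(rng.normal(32.0, 11.6), 20, 55))
        sex = "M" if rng.random() < 0.24 else "F"
        demo.append({"subject_id": sid, "age": age, "sex": sex})
        for scale, (mu, sd) in DEFAULT_SCALES.items():
            pre = rng.normal(mu, sd)
            for session in SESSIONS:
                rows.append({"subject_id": sid, "group": "control",
                             "session": session, "scale": scale,
                             "score": pre + (rng.normal(0.0, config.behavior_noise_sd)
                                             if session == "post" else 0.0)})
    return BehavioralTable(pd.DataFrame(rows), pd.DataFrame(demo))


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------

def discard_initial_volumes(ts: ROITimeSeriesSet,
                            n_discard: int) -> ROITimeSeriesSet:
    """Drop the first ``n_discard`` timepoints (scanner-equilibration
    volumes); a 212-volume series with the default 10 discarded retains
    202."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= ts.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_timepoints} volumes")
    return ROITimeSeriesSet(ts.subject_id, ts.session,
                            ts.data[n_discard:].copy(), ts.region_labels)


def apply_motion_exclusion(traces: Sequence[MotionTrace],
                           threshold_mm: float = MOTION_THRESHOLD_MM
                           ) -> tuple[list[str], list[str]]:
    """Partition subjects into (kept, excluded) by head motion.

    A subject is excluded iff the maximum absolute translation in ANY of
    its sessions strictly exceeds ``threshold_mm``; exactly at the
    threshold is kept.  Rotations are not consulted.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    worst: dict[str, float] = {}
    order: list[str] = []
    for tr in traces:
        if tr.subject_id not in worst:
            order.append(tr.subject_id)
            worst[tr.subject_id] = tr.max_abs_translation
        else:
            worst[tr.subject_id] = max(worst[tr.subject_id],
                                       tr.max_abs_translation)
    kept = [sid for sid in order if worst[sid] <= threshold_mm]
    excluded = [sid for sid in order if worst[sid] > threshold_mm]
    return kept, excluded


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_timeseries(ts: ROITimeSeriesSet, directory) -> str:
    """Write one subject-session series as ``{subject}_{session}.tsv``
    (header row of region labels)."""
    from pathlib import Path
    path = Path(directory) / f"{ts.subject_id}_{ts.session}.tsv"
    pd.DataFrame(ts.data, columns=list(ts.region_labels)).to_csv(
        path, sep="\t", index=False, float_format="%.6f")
    return str(path)


def read_timeseries(path, subject_id: str | None = None,
                    session: str | None = None) -> ROITimeSeriesSet:
    from pathlib import Path
    path = Path(path)
    if subject_id is None or session is None:
        stem = path.stem
        subject_id, _, session = stem.rpartition("_")
    df = pd.read_csv(path, sep="\t")
    return ROITimeSeriesSet(subject_id, session, df.to_numpy(),
                            tuple(df.columns))


def write_motion(trace: MotionTrace, directory) -> str:
    from pathlib import Path
    path = Path(directory) / f"{trace.subject_id}_{trace.session}_motion.tsv"
    np.savetxt(path, trace.as_matrix(), delimiter="\t", fmt="%.6f")
    return str(path)


def read_motion(path, subject_id: str, session: str) -> MotionTrace:
    m = np.loadtxt(path, delimiter="\t")
    return MotionTrace(subject_id, session, m[:, :3], m[:, 3:])
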