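"""Least-squares superposition and dual-mode RMSD trajectory analysis.

Two RMSD conventions are supported.  An *LS-Fit* series superposes each
frame on the reference over a fit selection before measuring; when the fit
and measure selections coincide this is the familiar minimal RMSD of that
atom set.  A *No-Fit* series applies only the transform obtained from the
fit selection (typically the protein secondary structures) and then
measures the target set (typically the ligand) with no further fitting, so
it includes the target's translational and rotational motion relative to
the protein frame.  On top of the series sit equilibrium-onset detection,
conformational-cluster segmentation, open-state persistence, and a
symmetry-corrected ligand RMSD that minimizes over bond-graph
automorphisms (the fix for topologically equivalent atoms such as the two
oxygens of a nitro group, which naive RMSD treats as distinct).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import Selection, StructureFrame, Trajectory, select_atoms

__all__ = [
    "RigidTransform",
    "RmsdSeries",
    "ClusterSegmentation",
    "PersistenceResult",
    "SymmetryRmsd",
    "DegenerateFitError",
    "AutomorphismBudgetError",
    "kabsch",
    "kabsch_fit",
    "rmsd_series",
    "symmetry_corrected_rmsd",
    "equilibrium_onset",
    "segment_clusters",
    "open_state_persistence",
]


class DegenerateFitError(ValueError):
    """Fewer than 3 fit atoms, or a collinear fit set."""


class AutomorphismBudgetError(RuntimeError):
    """The bond graph has more automorphisms than the search budget allows."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x ↦ R·x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def _rmsd(p: np.ndarray, q: np.ndarray) -> float:
    d = p - q
    return float(np.sqrt(np.einsum("ij,ij->", d, d) / p.shape[0]))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns the rigid transform minimizing the RMSD between the point sets
    (correspondence by index) and that minimal RMSD.  A reflection is never
    returned, so a chiral set superposed on its mirror image keeps a
    nonzero residual.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise DegenerateFitError("need at least 3 fit atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transform = RigidTransform(R, t)
    return transform, _rmsd(transform.apply(P), Q)


def kabsch_fit(
    mobile: StructureFrame,
    reference: StructureFrame,
    fit_sel: Selection | str,
) -> tuple[RigidTransform, float]:
    """Least-squares fit of ``mobile`` onto ``reference`` over a selection."""
    idx = select_atoms(reference, fit_sel)
    if idx.size == 0:
        raise ValueError("fit selection is empty")
    idx_m = select_atoms(mobile, fit_sel)
    if idx_m.size != idx.size:
        raise ValueError("fit selection sizes differ between frames")
    return kabsch(mobile.coords[idx_m], reference.coords[idx])


@dataclass
class RmsdSeries:
    """RMSD vs simulation time for a named selection, in one of two modes."""

    mode: str
    fit_label: str
    measure_label: str
    times_ns: np.ndarray
    rmsd: np.ndarray

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        if self.times_ns.size != self.rmsd.size:
            raise ValueError("times and rmsd must have equal length")
        if self.times_ns.size > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.rmsd < 0):
            raise ValueError("rmsd must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times_ns,
                "rmsd_A": self.rmsd,
                "mode": self.mode,
                "fit_sel": self.fit_label,
                "measure_sel": self.measure_label,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def window(self, t0: float, t1: float) -> "RmsdSeries":
        m = (self.times_ns >= t0) & (self.times_ns <= t1)
        return RmsdSeries(
            self.mode, self.fit_label, self.measure_label, self.times_ns[m], self.rmsd[m]
        )


def rmsd_series(
    traj: Trajectory,
    reference: StructureFrame | None = None,
    fit_sel: Selection | str = "mainchain",
    measure_sel: Selection | str | None = None,
    mode: str = "ls_fit",
) -> RmsdSeries:
    """RMSD ~ simulation-time series in LS-Fit or No-Fit mode.

    Both modes first obtain the frame→reference transform by least-squares
    fitting on ``fit_sel``.  In ``ls_fit`` mode with ``measure_sel`` equal
    to ``fit_sel`` (the default) the measured RMSD is the minimal RMSD of
    that set; otherwise — and always in ``no_fit`` mode — the fit-set
    transform is applied and the measure set's RMSD is taken with no
    further fitting, so the measurement retains the measure set's motion
    relative to the fitted frame.
    """
    if mode not in ("ls_fit", "no_fit"):
        raise ValueError(f"unknown mode {mode!r}")
    reference = reference if reference is not None else traj.frames[0]
    measure_sel = measure_sel if measure_sel is not None else fit_sel
    idx_fit = select_atoms(reference, fit_sel)
    idx_meas = select_atoms(reference, measure_sel)
    if idx_fit.size == 0 or idx_meas.size == 0:
        raise ValueError("fit and measure selections must be nonempty")
    same = idx_fit.size == idx_meas.size and np.array_equal(idx_fit, idx_meas)
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        transform, fit_rmsd = kabsch(frame.coords[idx_fit], reference.coords[idx_fit])
        if mode == "ls_fit" and same:
            out[k] = fit_rmsd
        else:
            moved = transform.apply(frame.coords[idx_meas])
            out[k] = _rmsd(moved, reference.coords[idx_meas])
    return RmsdSeries(
        mode=mode,
        fit_label=str(fit_sel),
        measure_label=str(measure_sel),
        times_ns=traj.times_ns,
        rmsd=out,
    )


# ---------------------------------------------------------------------------
# Symmetry-corrected RMSD
# ---------------------------------------------------------------------------


@dataclass
class SymmetryRmsd:
    """Symmetry-corrected RMSD with the naive value it improves on."""

    corrected: float
    naive: float
    n_automorphisms: int
    best_mapping: dict[int, int]


def _element_match(a: dict, b: dict) -> bool:
    return a.get("element") == b.get("element")


def symmetry_corrected_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    graph: nx.Graph,
    *,
    fit: bool = True,
    max_automorphisms: int = 10_000,
) -> SymmetryRmsd:
    """Minimum RMSD over element-preserving bond-graph automorphisms.

    ``graph`` is the shared bond topology: nodes are atom indices into both
    coordinate arrays, with an ``element`` attribute; edges are bonds.
    Topologically equivalent atoms (e.g. the two oxygens of a nitro group)
    yield nontrivial automorphisms, and the naive index-matched RMSD can be
    grossly inflated when such atoms swap; the corrected value minimizes
    over all consistent relabelings (exhaustive up to the budget).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("mobile and reference must have the same shape")
    if set(graph.nodes) != set(range(P.shape[0])):
        raise ValueError("graph nodes must be atom indices 0..n-1")

    def score(perm: np.ndarray) -> float:
        permuted = P[perm]
        if fit:
            try:
                _, r = kabsch(permuted, Q)
                return r
            except DegenerateFitError:
                pass
        return _rmsd(permuted, Q)

    matcher = nx.algorithms.isomorphism.GraphMatcher(graph, graph, node_match=_element_match)
    identity = np.arange(P.shape[0])
    naive = score(identity)
    best = naive
    best_mapping = {i: i for i in range(P.shape[0])}
    count = 0
    for mapping in matcher.isomorphisms_iter():
        count += 1
        if count > max_automorphisms:
            raise AutomorphismBudgetError(
                f"more than {max_automorphisms} automorphisms; raise the budget "
                "or prune the graph"
            )
        perm = np.array([mapping[i] for i in range(P.shape[0])])
        r = score(perm)
        if r < best:
            best = r
            best_mapping = dict(mapping)
    return SymmetryRmsd(
        corrected=float(best),
        naive=float(naive),
        n_automorphisms=count,
        best_mapping=best_mapping,
    )


# ---------------------------------------------------------------------------
# Series analytics: onset, clusters, persistence
# ---------------------------------------------------------------------------


def equilibrium_onset(
    series: RmsdSeries, window_ns: float = 10.0, band: float = 1.0
) -> float | None:
    """Earliest time after which every sliding window stays within ``band``.

    A window is the sample set in [t, t + window_ns] (only windows fully
    inside the series are considered).  Returns the start time of the first
    window such that it and every later window has max − min ≤ band, or
    ``None`` when the series never settles.
    """
    t, x = series.times_ns, series.rmsd
    if t[-1] - t[0] < 2.0 * window_ns:
        raise ValueError("series must span at least twice the window")
    starts = np.flatnonzero(t + window_ns <= t[-1] + 1e-12)
    ok = np.empty(starts.size, dtype=bool)
    for k, s in enumerate(starts):
        in_win = (t >= t[s]) & (t <= t[s] + window_ns + 1e-12)
        vals = x[in_win]
        ok[k] = vals.max() - vals.min() <= band
    if not ok.any():
        return None
    bad = np.flatnonzero(~ok)
    if bad.size == 0:
        return float(t[starts[0]])
    first_good = bad[-1] + 1
    if first_good >= starts.size:
        return None
    return float(t[starts[first_good]])


@dataclass
class ClusterSegmentation:
    """Partition of an RMSD series into conformational clusters."""

    boundaries_ns: list[float]
    representatives: list[int]
    mean_rmsd: list[float]

    @property
    def n_clusters(self) -> int:
        return len(self.mean_rmsd)


def _medoid(values: np.ndarray, offset: int) -> int:
    # 1-D medoid: minimal summed absolute deviation, earliest index on ties
    costs = np.abs(values[:, None] - values[None, :]).sum(axis=1)
    return offset + int(np.argmin(costs))


def segment_clusters(
    series: RmsdSeries, min_dwell_ns: float = 10.0, jump: float = 1.5
) -> ClusterSegmentation:
    """Change-point segmentation of an equilibrated RMSD series.

    A boundary is placed where the median over the following
    ``min_dwell_ns`` differs from the median over the preceding
    ``min_dwell_ns`` by at least ``jump`` Å; boundaries are picked greedily
    by shift size and must dwell at least ``min_dwell_ns`` apart.  Each
    segment's representative frame is its RMSD medoid (earliest on ties).
    """
    t, x = series.times_ns, series.rmsd
    n = t.size
    shift = np.zeros(n)
    for i in range(1, n):
        left = (t >= t[i] - min_dwell_ns) & (t < t[i])
        right = (t >= t[i]) & (t < t[i] + min_dwell_ns)
        if t[i] - min_dwell_ns < t[0] - 1e-12 or t[i] + min_dwell_ns > t[-1] + 1e-12:
            continue
        if left.sum() == 0 or right.sum() == 0:
            continue
        shift[i] = abs(np.median(x[right]) - np.median(x[left]))
    boundaries: list[int] = []
    available = shift.copy()
    while True:
        i = int(np.argmax(available))
        if available[i] < jump:
            break
        # the median shift plateaus around a clean step: snap the boundary to
        # the largest single-sample jump inside the detection window
        near = np.flatnonzero((np.abs(t - t[i]) < min_dwell_ns) & (np.arange(n) > 0))
        if near.size:
            local = np.abs(np.diff(x))
            i = int(near[np.argmax(local[near - 1])])
        boundaries.append(i)
        suppress = np.abs(t - t[i]) < min_dwell_ns
        available[suppress] = 0.0
    boundaries.sort()
    edges = [0] + boundaries + [n]
    reps, means = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        reps.append(_medoid(x[a:b], a))
        means.append(float(x[a:b].mean()))
    bounds_ns = [float(t[0])] + [float(t[i]) for i in boundaries] + [float(t[-1])]
    return ClusterSegmentation(boundaries_ns=bounds_ns, representatives=reps, mean_rmsd=means)


@dataclass
class PersistenceResult:
    """How long a series stayed at (below threshold of) its reference state."""

    duration_ns: float
    censored: bool


def open_state_persistence(series: RmsdSeries, threshold: float = 3.0) -> PersistenceResult:
    """Time the series remains below ``threshold`` before sustained exceedance.

    The open state is lost at the first sample from which the RMSD stays
    above the threshold to the end of the series (single-frame spikes that
    recover do not end it).  If the series never sustains an exceedance the
    full span is returned flagged as censored.
    """
    t, x = series.times_ns, series.rmsd
    above = x > threshold
    s = t.size
    for i in range(t.size - 1, -1, -1):
        if not above[i]:
            break
        s = i
    if s == t.size:
        return PersistenceResult(duration_ns=float(t[-1] - t[0]), censored=True)
    if s == 0:
        return PersistenceResult(duration_ns=0.0, censored=False)
    return PersistenceResult(duration_ns=float(t[s - 1] - t[0]), censored=False)
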