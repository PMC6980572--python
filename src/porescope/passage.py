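"""Permeant passage detection against the pore-lining lysine ring.

A passage ("passing-through") event is the permeant's center traversing
the plane of the five symmetry-equivalent lysines (local position 106 in
the pentamer) from one side to the other.  Because an unsigned
center-to-center distance cannot distinguish the two sides, events are
defined on the *signed* axial offset with a hysteresis band: the offset
must first exceed +h (resp. −h) and subsequently pass beyond −h (resp.
+h); jitter that stays inside ±h never counts.  Crossing times are
linearly interpolated at zero offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Selection, StructureFrame, SubunitMap, Trajectory, select_atoms
from .geometry import IncompleteRingError, _ring_residue_centers

__all__ = [
    "PassageTrace",
    "PassageEvent",
    "DEFAULT_HYSTERESIS",
    "permeant_ring_trace",
    "count_passages",
    "success_summary",
]

#: Default hysteresis half-width in Å for event detection.
DEFAULT_HYSTERESIS = 5.0


@dataclass
class PassageTrace:
    """Per-frame signed axial offset and unsigned distance to the ring center."""

    times_ns: np.ndarray
    offset: np.ndarray
    distance: np.ndarray
    ring_position: int = 106

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        if not (self.times_ns.size == self.offset.size == self.distance.size):
            raise ValueError("trace columns must have equal length")
        if self.times_ns.size > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ns": self.times_ns, "offset_A": self.offset, "distance_A": self.distance}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def reversed_time(self) -> "PassageTrace":
        t = self.times_ns
        return PassageTrace(
            times_ns=t[-1] - t[::-1],
            offset=self.offset[::-1].copy(),
            distance=self.distance[::-1].copy(),
            ring_position=self.ring_position,
        )


@dataclass(frozen=True)
class PassageEvent:
    """One completed traversal of the ring plane."""

    crossing_time_ns: float
    direction: str  # "+z" or "-z"
    pre_dwell_ns: float
    post_dwell_ns: float


def _best_fit_normal(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]


def permeant_ring_trace(
    traj: Trajectory,
    permeant_sel: Selection | str,
    ring_position: int = 106,
    smap: SubunitMap | None = None,
    policy: str = "heavy",
) -> PassageTrace:
    """Signed axial offset and unsigned distance of the permeant to the ring.

    The ring axis is the best-fit plane normal of the five residue centers,
    sign-fixed toward the first frame's +z so that the offset sign is
    stable under channel tilt; the offset is the projection of (permeant
    center − ring center) on that axis.
    """
    smap = smap or SubunitMap()
    idx_p = select_atoms(traj.frames[0], permeant_sel)
    if idx_p.size == 0:
        raise ValueError("permeant selection is empty")
    offsets = np.empty(traj.n_frames)
    dists = np.empty(traj.n_frames)
    ref_axis: np.ndarray | None = None
    for k, frame in enumerate(traj.frames):
        try:
            centers = _ring_residue_centers(frame, ring_position, smap, policy)
        except IncompleteRingError as exc:
            raise IncompleteRingError(f"frame {k}: {exc}") from None
        rc = centers.mean(axis=0)
        axis = _best_fit_normal(centers)
        if ref_axis is None:
            if axis[2] < 0:
                axis = -axis
            ref_axis = axis
        elif np.dot(axis, ref_axis) < 0:
            axis = -axis
        pc = frame.coords[idx_p].mean(axis=0)
        rel = pc - rc
        offsets[k] = float(np.dot(rel, axis))
        dists[k] = float(np.linalg.norm(rel))
    return PassageTrace(
        times_ns=traj.times_ns, offset=offsets, distance=dists, ring_position=ring_position
    )


def _interp_zero(t0: float, x0: float, t1: float, x1: float) -> float:
    if x1 == x0:
        return t0
    return t0 + (t1 - t0) * (0.0 - x0) / (x1 - x0)


def count_passages(
    trace: PassageTrace, hysteresis: float = DEFAULT_HYSTERESIS
) -> tuple[int, list[PassageEvent]]:
    """Hysteresis event count on the signed axial offset.

    The detector arms when the offset leaves the ±``hysteresis`` band; an
    event fires each time the armed side switches, i.e. the permeant has
    fully traversed from beyond one band edge to beyond the other.
    Crossing times are interpolated at zero offset from the bracketing
    sign change.
    """
    if hysteresis <= 0:
        raise ValueError("hysteresis must be positive")
    t, x = trace.times_ns, trace.offset
    if t.size < 2:
        raise ValueError("trace needs at least 2 samples")
    armed = 0  # -1, 0, +1: side beyond the band last visited
    last_zero = None  # most recent zero-crossing time
    events: list[PassageEvent] = []
    for k in range(t.size):
        if k > 0 and np.sign(x[k]) != np.sign(x[k - 1]) and x[k] != x[k - 1]:
            last_zero = _interp_zero(t[k - 1], x[k - 1], t[k], x[k])
        side = 1 if x[k] >= hysteresis else (-1 if x[k] <= -hysteresis else 0)
        if side != 0:
            if armed != 0 and side != armed:
                cross = last_zero if last_zero is not None else t[k]
                events.append(
                    PassageEvent(
                        crossing_time_ns=float(cross),
                        direction="+z" if side > 0 else "-z",
                        pre_dwell_ns=0.0,
                        post_dwell_ns=0.0,
                    )
                )
            armed = side
    # dwell bookkeeping between consecutive events / trace edges
    out = []
    for i, ev in enumerate(events):
        pre = ev.crossing_time_ns - (events[i - 1].crossing_time_ns if i else t[0])
        post = (events[i + 1].crossing_time_ns if i + 1 < len(events) else t[-1]) - (
            ev.crossing_time_ns
        )
        out.append(
            PassageEvent(
                crossing_time_ns=ev.crossing_time_ns,
                direction=ev.direction,
                pre_dwell_ns=float(pre),
                post_dwell_ns=float(post),
            )
        )
    return len(out), out


def success_summary(runs: Sequence[tuple[object, int]]) -> pd.DataFrame:
    """Per-run event table with success fraction and binomial SE.

    A run is successful iff it produced at least one passage event.  The
    returned table carries one row per run plus the summary columns
    ``success_fraction`` and ``success_se`` (identical on every row).
    """
    if not runs:
        raise ValueError("need at least one run")
    labels = [str(cfg) for cfg, _ in runs]
    counts = np.array([int(n) for _, n in runs])
    success = counts >= 1
    p = float(success.mean())
    se = float(np.sqrt(p * (1.0 - p) / counts.size))
    return pd.DataFrame(
        {
            "run": labels,
            "n_events": counts,
            "successful": success,
            "success_fraction": p,
            "success_se": se,
        }
    )
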