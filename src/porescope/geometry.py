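"""Residue-based channel radius analysis for pentameric channels.

The channel radius parameter r at a residue position is the mean distance
between the geometric center of the five symmetry-equivalent residues (one
per chain) and the geometric centers of the individual residues; the larger
r, the more open the pore at that position.  Profiles over a position range
(default 10–40, the pore-lining stretch) are averaged over trajectory
frames with a standard-error spread, and Δr compares two scenario profiles
elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import StructureFrame, SubunitMap, Trajectory

__all__ = [
    "RadiusProfile",
    "DeltaProfile",
    "IncompleteRingError",
    "residue_center",
    "ring_center",
    "channel_radius",
    "radius_profile",
    "delta_profile",
    "DEFAULT_POSITIONS",
]

DEFAULT_POSITIONS = range(10, 41)

_POLICIES = ("heavy", "all", "CA")


class IncompleteRingError(ValueError):
    """A residue ring is missing one or more of its five chains."""


def _chain_for_ordinal(frame: StructureFrame, ordinal: int) -> str:
    chains = list(dict.fromkeys(frame.chain_ids))
    if ordinal > len(chains):
        raise IncompleteRingError(f"frame has only {len(chains)} chains")
    return chains[ordinal - 1]


def _policy_mask(frame: StructureFrame, policy: str) -> np.ndarray:
    if policy == "heavy":
        return frame.elements != "H"
    if policy == "all":
        return np.ones(frame.n_atoms, dtype=bool)
    if policy == "CA":
        return frame.atom_names == "CA"
    raise ValueError(f"unknown atom policy {policy!r}; expected one of {_POLICIES}")


def residue_center(
    frame: StructureFrame, chain_id: str, local_index: int, policy: str = "heavy"
) -> np.ndarray:
    """Unweighted geometric center of one residue's included atoms."""
    mask = (
        (frame.chain_ids == chain_id)
        & (frame.residue_local_indices == local_index)
        & _policy_mask(frame, policy)
    )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise IncompleteRingError(
            f"residue {local_index} of chain {chain_id} has no atoms under policy {policy!r}"
        )
    return frame.coords[idx].mean(axis=0)


def _ring_residue_centers(
    frame: StructureFrame, position: int, smap: SubunitMap, policy: str
) -> np.ndarray:
    centers = []
    for ordinal in range(1, smap.n_chains + 1):
        chain = _chain_for_ordinal(frame, ordinal)
        centers.append(residue_center(frame, chain, position, policy))
    return np.asarray(centers)


def ring_center(
    frame: StructureFrame,
    position: int,
    smap: SubunitMap | None = None,
    policy: str = "heavy",
) -> np.ndarray:
    """Geometric center of the five symmetry-equivalent residues at ``position``."""
    smap = smap or SubunitMap()
    return _ring_residue_centers(frame, position, smap, policy).mean(axis=0)


def channel_radius(
    traj: Trajectory | StructureFrame,
    position: int,
    smap: SubunitMap | None = None,
    policy: str = "heavy",
) -> tuple[float, float]:
    """Channel radius r and its standard error over frames at one position.

    Per frame, r_f is the mean over the five equivalent residues of the
    distance between each residue center and the ring center; r averages
    r_f over frames and the spread is the SE (sd/√n; 0 for one frame).
    """
    if isinstance(traj, StructureFrame):
        traj = Trajectory([traj])
    smap = smap or SubunitMap()
    per_frame = []
    for k, frame in enumerate(traj.frames):
        try:
            centers = _ring_residue_centers(frame, position, smap, policy)
        except IncompleteRingError as exc:
            raise IncompleteRingError(f"frame {k}: {exc}") from None
        rc = centers.mean(axis=0)
        per_frame.append(float(np.linalg.norm(centers - rc, axis=1).mean()))
    vals = np.asarray(per_frame)
    r = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return r, se


@dataclass
class RadiusProfile:
    """Per-position channel radius with SE spread for one scenario."""

    scenario: str
    positions: np.ndarray
    r: np.ndarray
    spread: np.ndarray
    n_frames: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario,
                "position": self.positions,
                "r_A": self.r,
                "se_A": self.spread,
                "n_frames": self.n_frames,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class DeltaProfile:
    """Elementwise difference of two radius profiles (minuend − subtrahend)."""

    minuend: str
    subtrahend: str
    positions: np.ndarray
    delta_r: np.ndarray
    spread: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minuend": self.minuend,
                "subtrahend": self.subtrahend,
                "position": self.positions,
                "delta_r_A": self.delta_r,
                "se_A": self.spread,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def radius_profile(
    traj: Trajectory | StructureFrame,
    positions: Sequence[int] = DEFAULT_POSITIONS,
    smap: SubunitMap | None = None,
    policy: str = "heavy",
    scenario: str = "",
) -> RadiusProfile:
    """Channel-radius profile over a residue-position range."""
    if isinstance(traj, StructureFrame):
        traj = Trajectory([traj])
    positions = np.asarray(sorted(positions), dtype=int)
    r = np.empty(positions.size)
    se = np.empty(positions.size)
    for k, pos in enumerate(positions):
        r[k], se[k] = channel_radius(traj, int(pos), smap, policy)
    return RadiusProfile(
        scenario=scenario, positions=positions, r=r, spread=se, n_frames=traj.n_frames
    )


def delta_profile(a: RadiusProfile, b: RadiusProfile) -> DeltaProfile:
    """Δr = a − b per position; spreads combine in quadrature."""
    if a.positions.size != b.positions.size or np.any(a.positions != b.positions):
        raise ValueError("profiles cover different position ranges")
    return DeltaProfile(
        minuend=a.scenario,
        subtrahend=b.scenario,
        positions=a.positions.copy(),
        delta_r=a.r - b.r,
        spread=np.sqrt(a.spread**2 + b.spread**2),
    )
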