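"""Synthetic structures, trajectories and parameter tables with known ground truth.

Every generator is seed-deterministic.  The pentamer builder produces an
exactly five-fold-symmetric channel whose per-position ring radius is the
requested R(i), so the geometry analyses can be validated to machine
precision; the crossing-trace builder produces a permeant z-trace whose
hysteresis crossing count is known by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import AtomRecord, StructureFrame, Trajectory
from .energetics import ForceFieldTable

__all__ = [
    "PentamerSpec",
    "LipidSlabSpec",
    "CrossingTraceSpec",
    "build_ideal_pentamer",
    "build_lipid_slab",
    "perturb_trajectory",
    "make_crossing_trace",
    "make_toy_ff",
    "add_ligand",
]

logger = logging.getLogger(__name__)

_CHAIN_IDS = "ABCDE"

# Per-residue atom offsets in the residue-local frame.  Each group sums to
# the zero vector so that the residue centroid (heavy-only or all-atom)
# coincides exactly with the constructed ring point.
_MAINCHAIN_OFFSETS = {
    "N": np.array([0.8, 0.5, 0.0]),
    "CA": np.array([0.0, -0.5, 0.4]),
    "C": np.array([-0.8, 0.5, 0.0]),
    "O": np.array([0.0, -0.5, -0.4]),
}
_H_OFFSETS = {
    "H1": np.array([0.3, 0.9, 0.6]),
    "H2": np.array([-0.3, -0.9, -0.6]),
}


@dataclass(frozen=True)
class PentamerSpec:
    """Geometry of an ideal five-fold-symmetric pentameric channel.

    ``radius`` may be a constant (Å), a sequence indexed by local residue
    position, or a callable R(i); it sets the distance of each residue's
    geometric center from the channel axis.  ``axial_spacing`` is the rise
    per residue along z (Å); ``twist_per_residue`` an optional azimuthal
    advance (radians).
    """

    chain_length: int = 136
    radius: float | Sequence[float] | Callable[[int], float] = 8.0
    axial_spacing: float = 1.5
    atoms_per_residue: int = 1
    include_hydrogens: bool = False
    twist_per_residue: float = 0.0
    seed: int = 0

    def radius_at(self, position: int) -> float:
        if callable(self.radius):
            r = float(self.radius(position))
        elif np.isscalar(self.radius):
            r = float(self.radius)
        else:
            r = float(self.radius[position - 1])
        if r <= 0:
            raise ValueError(f"ring radius at position {position} must be > 0, got {r}")
        return r


@dataclass(frozen=True)
class LipidSlabSpec:
    """A flat slab of lipid surrogate sites for membrane-offset bookkeeping."""

    center_z: float = 0.0
    thickness: float = 18.0
    n_sites: int = 200
    lateral_extent: float = 60.0
    seed: int = 0


@dataclass(frozen=True)
class CrossingTraceSpec:
    """A permeant z-trace crossing the ring plane a known number of times."""

    n_crossings: int = 3
    dwell_ns: float = 3.0
    noise_sd: float = 0.3
    amplitude: float = 12.0
    dt_ns: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crossings < 0:
            raise ValueError("n_crossings must be >= 0")
        if self.amplitude <= 0 or self.dwell_ns <= 0 or self.dt_ns <= 0:
            raise ValueError("amplitude, dwell_ns and dt_ns must be positive")


def _rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_ideal_pentamer(spec: PentamerSpec) -> StructureFrame:
    """Construct the ideal pentamer frame.

    Residue i of chain 1 is centred at (R(i)·cos φᵢ, R(i)·sin φᵢ, i·spacing);
    chain k is chain 1 rotated by 72°·(k−1) about z, so the structure is
    exactly five-fold symmetric and the channel-radius analysis recovers
    R(i) to machine precision.
    """
    atom_specs: list[tuple[str, str, np.ndarray]] = [("CA", "C", np.zeros(3))]
    if spec.atoms_per_residue >= 4:
        atom_specs = [
            ("N", "N", _MAINCHAIN_OFFSETS["N"]),
            ("CA", "C", _MAINCHAIN_OFFSETS["CA"]),
            ("C", "C", _MAINCHAIN_OFFSETS["C"]),
            ("O", "O", _MAINCHAIN_OFFSETS["O"]),
        ]
    if spec.include_hydrogens:
        atom_specs = atom_specs + [(n, "H", off) for n, off in _H_OFFSETS.items()]

    atoms: list[AtomRecord] = []
    for k in range(5):
        rot = _rotation_z(2.0 * np.pi * k / 5.0)
        for i in range(1, spec.chain_length + 1):
            phi = spec.twist_per_residue * (i - 1)
            center = np.array(
                [
                    spec.radius_at(i) * np.cos(phi),
                    spec.radius_at(i) * np.sin(phi),
                    i * spec.axial_spacing,
                ]
            )
            for name, element, off in atom_specs:
                atoms.append(
                    AtomRecord(
                        atom_name=name,
                        element=element,
                        chain_id=_CHAIN_IDS[k],
                        residue_local_index=i,
                        residue_name="ALA",
                        coords=rot @ (center + off),
                    )
                )
    return StructureFrame(atoms, time_ns=0.0)


def build_lipid_slab(spec: LipidSlabSpec) -> StructureFrame:
    """Uniform random lipid surrogate sites within thickness/2 of the slab center."""
    rng = np.random.default_rng(spec.seed)
    xy = rng.uniform(-spec.lateral_extent / 2, spec.lateral_extent / 2, size=(spec.n_sites, 2))
    z = spec.center_z + rng.uniform(-spec.thickness / 2, spec.thickness / 2, size=spec.n_sites)
    atoms = [
        AtomRecord(
            atom_name="P",
            element="P",
            chain_id="M",
            residue_local_index=i + 1,
            residue_name="POP",
            coords=np.array([xy[i, 0], xy[i, 1], z[i]]),
        )
        for i in range(spec.n_sites)
    ]
    return StructureFrame(atoms, time_ns=0.0)


def perturb_trajectory(
    frame: StructureFrame,
    n_frames: int,
    noise_sd: float,
    seed: int = 0,
    dt_ns: float = 0.1,
) -> Trajectory:
    """I.i.d. isotropic Gaussian displacement per atom per frame.

    Frame 0 is the unperturbed input; subsequent frames add fresh noise to
    the input (not to each other), matching the uncorrelated-noise model the
    analyses assume.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    frames = [frame.with_coords(frame.coords.copy(), time_ns=0.0)]
    for k in range(1, n_frames):
        noise = rng.normal(0.0, noise_sd, size=frame.coords.shape) if noise_sd > 0 else 0.0
        frames.append(frame.with_coords(frame.coords + noise, time_ns=k * dt_ns))
    return Trajectory(frames)


def make_crossing_trace(spec: CrossingTraceSpec, ring_z: float = 0.0) -> Trajectory:
    """Single-permeant trajectory whose z-trace crosses ``ring_z`` exactly
    ``spec.n_crossings`` times at the documented ±5 Å hysteresis.

    The trace is piecewise linear between alternating dwell plateaus at
    ±amplitude, plus Gaussian jitter; with amplitude well above the
    hysteresis band and jitter well below it the count is exact by
    construction.  For ``n_crossings = 0`` the permeant approaches the ring
    from one side and retreats without switching sides.
    """
    if spec.amplitude <= spec.noise_sd:
        logger.warning(
            "crossing-trace amplitude %.3g <= noise sd %.3g: ground-truth count "
            "may be violated",
            spec.amplitude,
            spec.noise_sd,
        )
    A = spec.amplitude
    if spec.n_crossings == 0:
        way_t = np.array([0.0, spec.dwell_ns, 2.0 * spec.dwell_ns])
        way_z = np.array([-A, -2.0, -A])
    else:
        # n+1 alternating plateaus produce exactly n side switches
        way_t = np.arange(spec.n_crossings + 1) * spec.dwell_ns
        way_z = np.array([A * (-1.0) ** (k + 1) for k in range(spec.n_crossings + 1)])
    duration = way_t[-1]
    t = np.arange(0.0, duration + 0.5 * spec.dt_ns, spec.dt_ns)
    z = np.interp(t, way_t, way_z)
    rng = np.random.default_rng(spec.seed)
    z = z + rng.normal(0.0, spec.noise_sd, size=t.shape)
    lateral = rng.normal(0.0, spec.noise_sd, size=(t.size, 2))
    frames = []
    for k in range(t.size):
        atom = AtomRecord(
            atom_name="DHS",
            element="C",
            chain_id="X",
            residue_local_index=1,
            residue_name="DHS",
            coords=np.array([lateral[k, 0], lateral[k, 1], ring_z + z[k]]),
        )
        frames.append(StructureFrame([atom], time_ns=float(t[k])))
    return Trajectory(frames)


def add_ligand(
    frame: StructureFrame,
    center: Sequence[float],
    n_atoms: int = 6,
    radius: float = 1.5,
    seed: int = 0,
) -> StructureFrame:
    """Append a small ring-shaped ligand (residue ``LIG``, chain ``X``) to a frame."""
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    atoms = frame.atoms
    for k in range(n_atoms):
        ang = 2.0 * np.pi * k / n_atoms
        pos = center + np.array([radius * np.cos(ang), radius * np.sin(ang), 0.0])
        pos = pos + rng.normal(0.0, 0.05, size=3)
        atoms.append(
            AtomRecord(
                atom_name=f"L{k + 1}",
                element="O" if k % 2 else "C",
                chain_id="X",
                residue_local_index=1,
                residue_name="LIG",
                coords=pos,
            )
        )
    return StructureFrame(atoms, time_ns=frame.time_ns, box=frame.box)


def make_toy_ff(
    frame: StructureFrame,
    preset: str = "pentamer_ligand",
    seed: int = 0,
) -> ForceFieldTable:
    """Toy per-atom charge/LJ/GB parameter table for the energetics tests.

    Presets
    -------
    ``born_ion``
        Single +1 e ion with a 2.0 Å intrinsic GB radius (the Born closed
        form applies exactly).
    ``dimer``
        Two opposite ±0.5 e charges (net neutral).
    ``pentamer_ligand``
        Receptor atoms get small zero-sum-per-residue charges; ligand atoms
        (residue names in the ligand class) get alternating ±0.4 e polar
        charges and are flagged in ``is_ligand``.
    """
    n = frame.n_atoms
    rng = np.random.default_rng(seed)
    if preset == "born_ion":
        if n != 1:
            raise ValueError("born_ion preset expects a single-atom frame")
        return ForceFieldTable(
            charges=np.array([1.0]),
            lj_radius=np.array([2.0]),
            lj_eps=np.array([0.1]),
            gb_radius=np.array([2.0]),
            gb_screen=np.array([0.8]),
        )
    if preset == "dimer":
        if n != 2:
            raise ValueError("dimer preset expects a two-atom frame")
        return ForceFieldTable(
            charges=np.array([0.5, -0.5]),
            lj_radius=np.array([1.7, 1.7]),
            lj_eps=np.array([0.15, 0.15]),
            gb_radius=np.array([1.5, 1.5]),
            gb_screen=np.array([0.8, 0.8]),
        )
    if preset == "pentamer_ligand":
        from .core import LIGAND_RESNAMES

        is_ligand = np.isin(frame.residue_names, list(LIGAND_RESNAMES))
        charges = np.zeros(n)
        # receptor: small random charges, zero-summed within each residue
        rec = np.flatnonzero(~is_ligand)
        q = rng.uniform(-0.2, 0.2, size=rec.size)
        res_keys = [
            (str(frame.chain_ids[i]), int(frame.residue_local_indices[i])) for i in rec
        ]
        for key in set(res_keys):
            members = [j for j, k2 in enumerate(res_keys) if k2 == key]
            q[members] -= q[members].mean()
        charges[rec] = q
        # ligand: alternating polar charges, net neutral
        lig = np.flatnonzero(is_ligand)
        if lig.size:
            ql = 0.4 * np.array([(-1.0) ** k for k in range(lig.size)])
            ql -= ql.mean()
            charges[lig] = ql
        return ForceFieldTable(
            charges=charges,
            lj_radius=np.full(n, 1.7),
            lj_eps=np.full(n, 0.12),
            gb_radius=np.full(n, 1.6),
            gb_screen=np.full(n, 0.8),
            is_ligand=is_ligand,
        )
    raise ValueError(f"unknown force-field preset {preset!r}")
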