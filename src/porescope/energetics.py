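"""MM-GB(SA) endpoint energetics on trajectory snapshots.

The free energy of a species is assembled as

    G = E_ele + E_vdw + G_polar + G_nonpolar

with Coulomb/12-6 Lennard-Jones molecular-mechanics terms, a Hawkins
pairwise-descreening generalized Born polar solvation term, and the
SASA-based nonpolar term ΔG_nonpolar = 0.0054·SAS + 0.92 (kcal/mol, SAS in
Å²).  Binding free energies follow the single-trajectory approximation:
complex, receptor and ligand energies are all taken from the same complex
snapshots.  The configurational-entropy term is not computed; every report
flags it as absent.

The membrane enters in two ways: the per-snapshot membrane center offset
(mctrdz) between the protein and lipid-slab coordinate centers is recorded,
and membrane-on evaluations use the lipid dielectric ε_lip as the external
dielectric of the GB term (the ligand alone is always solvated in water,
ε = 80, membrane off).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Selection, StructureFrame, Trajectory, select_atoms

__all__ = [
    "COULOMB_K",
    "EV_PER_ANGSTROM_TO_KCAL",
    "ForceFieldTable",
    "SolvationConfig",
    "EnergyReport",
    "PoseRanking",
    "mm_energy",
    "effective_born_radii",
    "gb_polar",
    "sasa",
    "nonpolar_energy",
    "membrane_offset",
    "binding_free_energy",
    "residue_decomposition",
    "rank_poses",
    "subsample_snapshots",
]

logger = logging.getLogger(__name__)

#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB_K = 332.0636

#: 1 e·Volt/Å expressed in kcal/(mol·Å); connects field strengths in V/Å
#: to molecular-mechanics energetics.
EV_PER_ANGSTROM_TO_KCAL = 23.0605


@dataclass
class ForceFieldTable:
    """Per-atom charge, Lennard-Jones and generalized-Born parameters.

    ``lj_radius`` is Rmin/2 in Å (Lorentz–Berthelot: Rmin_ij = r_i + r_j,
    ε_ij = √(ε_i ε_j)); ``gb_radius`` the intrinsic Born radius in Å;
    ``gb_screen`` the dimensionless descreening scale factor.
    """

    charges: np.ndarray
    lj_radius: np.ndarray
    lj_eps: np.ndarray
    gb_radius: np.ndarray
    gb_screen: np.ndarray | None = None
    is_ligand: np.ndarray | None = None

    DEFAULT_SCREEN = 0.8

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        n = self.charges.size
        for name in ("lj_radius", "lj_eps", "gb_radius"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ValueError(f"{name} must have {n} entries")
            setattr(self, name, arr)
        if self.gb_screen is None:
            self.gb_screen = np.full(n, self.DEFAULT_SCREEN)
        else:
            self.gb_screen = np.asarray(self.gb_screen, dtype=float)
        if np.any(self.lj_radius <= 0) or np.any(self.gb_radius <= 0):
            raise ValueError("LJ and GB radii must be positive")

    @property
    def n_atoms(self) -> int:
        return self.charges.size

    def check_covers(self, frame: StructureFrame) -> None:
        if self.n_atoms != frame.n_atoms:
            raise ValueError(
                f"force-field table covers {self.n_atoms} atoms but the frame "
                f"has {frame.n_atoms}"
            )

    def subset(self, indices: np.ndarray) -> "ForceFieldTable":
        return ForceFieldTable(
            charges=self.charges[indices],
            lj_radius=self.lj_radius[indices],
            lj_eps=self.lj_eps[indices],
            gb_radius=self.gb_radius[indices],
            gb_screen=self.gb_screen[indices],
            is_ligand=None if self.is_ligand is None else self.is_ligand[indices],
        )

    def to_file(self, path: str | Path) -> None:
        """Write the whitespace-separated parameter table."""
        df = pd.DataFrame(
            {
                "atom_index": np.arange(1, self.n_atoms + 1),
                "q_e": self.charges,
                "lj_radius_A": self.lj_radius,
                "lj_eps_kcal": self.lj_eps,
                "gb_radius_A": self.gb_radius,
                "gb_screen": self.gb_screen,
            }
        )
        df.to_csv(path, sep=" ", index=False, float_format="%.6f")

    @classmethod
    def from_file(cls, path: str | Path) -> "ForceFieldTable":
        df = pd.read_csv(path, sep=r"\s+")
        return cls(
            charges=df["q_e"].to_numpy(),
            lj_radius=df["lj_radius_A"].to_numpy(),
            lj_eps=df["lj_eps_kcal"].to_numpy(),
            gb_radius=df["gb_radius_A"].to_numpy(),
            gb_screen=df["gb_screen"].to_numpy() if "gb_screen" in df else None,
        )


@dataclass(frozen=True)
class SolvationConfig:
    """Dielectric, membrane and surface-term configuration.

    ``eps_lipid`` replaces ``eps_water`` as the GB external dielectric when
    the implicit membrane is on; the slab thickness defaults to 18 Å and the
    per-snapshot center offset (mctrdz) is recorded alongside the energies.
    """

    eps_internal: float = 1.0
    eps_water: float = 80.0
    eps_lipid: float = 4.0
    membrane: bool = False
    membrane_thickness: float = 18.0
    sasa_probe: float = 1.4
    sasa_points: int = 960
    nonpolar_slope: float = 0.0054
    nonpolar_intercept: float = 0.92
    hotspot_cutoff: float = -1.0

    def __post_init__(self) -> None:
        if min(self.eps_internal, self.eps_water, self.eps_lipid) < 1.0:
            raise ValueError("dielectric constants must be >= 1")
        if self.membrane_thickness <= 0:
            raise ValueError("membrane thickness must be positive")

    @property
    def eps_external(self) -> float:
        return self.eps_lipid if self.membrane else self.eps_water


# ---------------------------------------------------------------------------
# Molecular-mechanics terms
# ---------------------------------------------------------------------------


def _pair_indices(
    n: int, group_a: np.ndarray | None, group_b: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    if group_a is None and group_b is None:
        ii, jj = np.triu_indices(n, k=1)
        return ii, jj
    if group_a is None or group_b is None:
        raise ValueError("give both groups or neither")
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if np.intersect1d(a, b).size:
        raise ValueError("groups overlap")
    ii = np.repeat(a, b.size)
    jj = np.tile(b, a.size)
    return ii, jj


def mm_energy(
    frame: StructureFrame,
    ff: ForceFieldTable,
    group_a: np.ndarray | None = None,
    group_b: np.ndarray | None = None,
) -> tuple[float, float]:
    """Coulomb and 12-6 Lennard-Jones energies, kcal/mol.

    With no groups, all unique intramolecular pairs are summed; with two
    disjoint groups only A–B cross pairs are counted.  No cutoffs, no
    minimization: energies are evaluated on the snapshot as given.
    """
    ff.check_covers(frame)
    ii, jj = _pair_indices(frame.n_atoms, group_a, group_b)
    if ii.size == 0:
        return 0.0, 0.0
    d = frame.coords[ii] - frame.coords[jj]
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    if np.any(r < 1e-6):
        raise ValueError("overlapping atoms (pair distance < 1e-6 Å)")
    e_ele = COULOMB_K * np.sum(ff.charges[ii] * ff.charges[jj] / r)
    rmin = ff.lj_radius[ii] + ff.lj_radius[jj]
    eps = np.sqrt(ff.lj_eps[ii] * ff.lj_eps[jj])
    s6 = (rmin / r) ** 6
    e_vdw = np.sum(eps * (s6 * s6 - 2.0 * s6))
    return float(e_ele), float(e_vdw)


# ---------------------------------------------------------------------------
# Hawkins generalized Born
# ---------------------------------------------------------------------------


def effective_born_radii(
    coords: np.ndarray, gb_radius: np.ndarray, gb_screen: np.ndarray
) -> np.ndarray:
    """Effective Born radii by Hawkins–Cramer–Truhlar pairwise descreening.

    For atom i with intrinsic radius ρᵢ the inverse effective radius is
    1/Rᵢ = 1/ρᵢ − Σⱼ Hᵢⱼ, the sum of analytic descreening integrals over
    the scaled neighbour spheres sⱼ = Sⱼ·ρⱼ.  Neighbours entirely inside
    atom i contribute nothing.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    rho = np.asarray(gb_radius, dtype=float)
    s = np.asarray(gb_screen, dtype=float) * rho
    inv_r = 1.0 / rho.copy()
    if n == 1:
        return rho.copy()
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    for i in range(n):
        rij = r[i]
        sj = s
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mask &= rij + sj > rho[i]  # neighbour pokes out of atom i
        if not np.any(mask):
            continue
        rm = rij[mask]
        sm = sj[mask]
        U = rm + sm
        L = np.maximum(rho[i], rm - sm)
        H = 0.5 * (
            (1.0 / L - 1.0 / U)
            + (rm / 4.0) * (1.0 / U**2 - 1.0 / L**2)
            + (1.0 / (2.0 * rm)) * np.log(L / U)
            + (sm**2 / (4.0 * rm)) * (1.0 / L**2 - 1.0 / U**2)
        )
        inv_r[i] -= H.sum()
    # a heavily descreened atom can drive 1/R <= 0; clamp to a large radius
    inv_r = np.maximum(inv_r, 1e-6)
    return 1.0 / inv_r


def _f_gb(r: np.ndarray, Ri: np.ndarray, Rj: np.ndarray) -> np.ndarray:
    rr = Ri * Rj
    return np.sqrt(r**2 + rr * np.exp(-(r**2) / (4.0 * rr)))


def gb_polar(
    frame: StructureFrame,
    ff: ForceFieldTable,
    config: SolvationConfig,
    indices: np.ndarray | None = None,
) -> float:
    """Generalized Born polar solvation free energy, kcal/mol.

    G_polar = −(k/2)·(1/ε_in − 1/ε_out)·Σᵢⱼ qᵢqⱼ/f_GB(rᵢⱼ, Rᵢ, Rⱼ), the
    double sum running over all ordered pairs including self terms
    (f_GB(0) = Rᵢ reduces each to the Born ion energy).
    """
    ff.check_covers(frame)
    if indices is not None:
        coords = frame.coords[indices]
        sub = ff.subset(np.asarray(indices, dtype=int))
    else:
        coords = frame.coords
        sub = ff
    pref = -0.5 * COULOMB_K * (1.0 / config.eps_internal - 1.0 / config.eps_external)
    if pref == 0.0:
        return 0.0
    R = effective_born_radii(coords, sub.gb_radius, sub.gb_screen)
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    f = _f_gb(r, R[:, None], R[None, :])
    q = sub.charges
    return float(pref * np.sum(q[:, None] * q[None, :] / f))


def _gb_cross(
    coords: np.ndarray,
    charges: np.ndarray,
    born: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    config: SolvationConfig,
) -> float:
    """GB interaction between two disjoint groups (each unordered pair once)."""
    pref = -COULOMB_K * (1.0 / config.eps_internal - 1.0 / config.eps_external)
    if pref == 0.0:
        return 0.0
    ca, cb = coords[idx_a], coords[idx_b]
    diff = ca[:, None, :] - cb[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    f = _f_gb(r, born[idx_a][:, None], born[idx_b][None, :])
    return float(pref * np.sum(charges[idx_a][:, None] * charges[idx_b][None, :] / f))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-spiral)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²) by Shrake–Rupley.

    Each atom's expanded sphere (radius + probe) is sampled with a fixed
    golden-spiral point set; points inside any neighbour's expanded sphere
    are buried.  Deterministic for a given ``n_points``.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    n = coords.shape[0]
    expanded = radii + probe
    unit = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    out = np.zeros(n)
    rmax = expanded.max()
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], expanded[i] + rmax) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 > expanded[j] ** 2
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed.mean()
    return out


def nonpolar_energy(
    sas: float, config: SolvationConfig | None = None
) -> float:
    """Nonpolar solvation term ΔG = slope·SAS + intercept (kcal/mol; SAS in Å²).

    With the default parameterization this is 0.0054·SAS + 0.92.
    """
    if sas < 0:
        raise ValueError("SAS must be non-negative")
    cfg = config or SolvationConfig()
    return cfg.nonpolar_slope * float(sas) + cfg.nonpolar_intercept


def membrane_offset(
    frame: StructureFrame,
    protein_sel: Selection | str,
    lipid_sel: Selection | str,
) -> float:
    """Membrane center offset mctrdz: protein center z minus lipid center z (Å)."""
    ip = select_atoms(frame, protein_sel)
    il = select_atoms(frame, lipid_sel)
    if ip.size == 0 or il.size == 0:
        raise ValueError("protein and lipid selections must be nonempty")
    return float(frame.coords[ip, 2].mean() - frame.coords[il, 2].mean())


# ---------------------------------------------------------------------------
# Species free energies, binding, decomposition
# ---------------------------------------------------------------------------


def _species_energy(
    frame: StructureFrame,
    ff: ForceFieldTable,
    indices: np.ndarray,
    config: SolvationConfig,
) -> dict[str, float]:
    sub_frame = StructureFrame(
        atom_names=frame.atom_names[indices],
        elements=frame.elements[indices],
        chain_ids=frame.chain_ids[indices],
        residue_local_indices=frame.residue_local_indices[indices],
        residue_names=frame.residue_names[indices],
        coords=frame.coords[indices],
        time_ns=frame.time_ns,
    )
    sub_ff = ff.subset(indices)
    e_ele, e_vdw = mm_energy(sub_frame, sub_ff)
    g_pol = gb_polar(sub_frame, sub_ff, config)
    per_atom_sas = sasa(
        sub_frame.coords, sub_ff.lj_radius, config.sasa_probe, config.sasa_points
    )
    g_np = nonpolar_energy(per_atom_sas.sum(), config)
    return {
        "E_ele": e_ele,
        "E_vdw": e_vdw,
        "G_polar": g_pol,
        "G_nonpolar": g_np,
        "G_total": e_ele + e_vdw + g_pol + g_np,
    }


_COMPONENTS = ("E_ele", "E_vdw", "G_polar", "G_nonpolar", "G_total")


@dataclass
class EnergyReport:
    """Averaged MM-GB(SA) components for complex, receptor, ligand and ΔG_bind.

    All energies kcal/mol.  ``entropy_included`` is always False: the
    configurational-entropy estimate is intentionally not part of this
    pipeline and the binding numbers are enthalpic totals.
    """

    complex: dict[str, float]
    receptor: dict[str, float]
    ligand: dict[str, float]
    delta: dict[str, float]
    delta_total: float
    delta_total_se: float
    n_snapshots: int
    config: SolvationConfig
    mctrdz: list[float] | None = None
    per_residue: pd.DataFrame | None = None
    entropy_included: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Components table mirroring an MM-PB/GBSA free-energy listing."""
        rows = []
        for species, comp in (
            ("complex", self.complex),
            ("receptor", self.receptor),
            ("ligand", self.ligand),
            ("delta", self.delta),
        ):
            rows.append({"species": species, **comp})
        return pd.DataFrame(rows)


def _as_frames(snapshots: Trajectory | Sequence[StructureFrame]) -> list[StructureFrame]:
    if isinstance(snapshots, Trajectory):
        return list(snapshots.frames)
    return list(snapshots)


def binding_free_energy(
    snapshots: Trajectory | Sequence[StructureFrame],
    receptor_sel: Selection | str,
    ligand_sel: Selection | str,
    ff: ForceFieldTable,
    config: SolvationConfig | None = None,
    lipid_sel: Selection | str | None = None,
) -> EnergyReport:
    """Single-trajectory MM-GBSA binding free energy over complex snapshots.

    ΔG_bind = ⟨G_complex − G_receptor − G_ligand⟩; each G sums E_ele, E_vdw,
    G_polar and G_nonpolar.  The receptor and complex use ``config`` as
    given (membrane on means ε_out = ε_lip); the isolated ligand is always
    evaluated in water (ε_out = 80, membrane off).  When ``lipid_sel`` is
    given the per-snapshot membrane center offset mctrdz is recorded.
    """
    cfg = config or SolvationConfig()
    frames = _as_frames(snapshots)
    if not frames:
        raise ValueError("need at least one snapshot")
    f0 = frames[0]
    ff.check_covers(f0)
    idx_r = select_atoms(f0, receptor_sel)
    idx_l = select_atoms(f0, ligand_sel)
    if idx_r.size == 0 or idx_l.size == 0:
        raise ValueError("receptor and ligand selections must be nonempty")
    if np.intersect1d(idx_r, idx_l).size:
        raise ValueError("receptor and ligand selections overlap")
    idx_c = np.sort(np.concatenate([idx_r, idx_l]))
    ligand_cfg = replace(cfg, membrane=False)  # ligand alone: water, no membrane

    acc = {sp: {c: [] for c in _COMPONENTS} for sp in ("complex", "receptor", "ligand")}
    deltas = []
    mctr: list[float] = []
    for frame in frames:
        e_c = _species_energy(frame, ff, idx_c, cfg)
        e_r = _species_energy(frame, ff, idx_r, cfg)
        e_l = _species_energy(frame, ff, idx_l, ligand_cfg)
        for comp in _COMPONENTS:
            acc["complex"][comp].append(e_c[comp])
            acc["receptor"][comp].append(e_r[comp])
            acc["ligand"][comp].append(e_l[comp])
        deltas.append(e_c["G_total"] - e_r["G_total"] - e_l["G_total"])
        if lipid_sel is not None:
            mctr.append(membrane_offset(frame, receptor_sel, lipid_sel))
    mean = {sp: {c: float(np.mean(v)) for c, v in comps.items()} for sp, comps in acc.items()}
    delta = {
        c: mean["complex"][c] - mean["receptor"][c] - mean["ligand"][c]
        for c in _COMPONENTS
    }
    deltas = np.asarray(deltas)
    se = float(deltas.std(ddof=1) / np.sqrt(len(deltas))) if len(deltas) > 1 else 0.0
    return EnergyReport(
        complex=mean["complex"],
        receptor=mean["receptor"],
        ligand=mean["ligand"],
        delta=delta,
        delta_total=float(deltas.mean()),
        delta_total_se=se,
        n_snapshots=len(frames),
        config=cfg,
        mctrdz=mctr or None,
    )


def residue_decomposition(
    snapshots: Trajectory | Sequence[StructureFrame],
    receptor_sel: Selection | str,
    ligand_sel: Selection | str,
    ff: ForceFieldTable,
    config: SolvationConfig | None = None,
    include_nonpolar: bool = True,
) -> pd.DataFrame:
    """Per-residue receptor–ligand interaction energies with hotspot flags.

    Each receptor residue receives its Coulomb and LJ cross terms with the
    ligand, its share of the GB cross term (complex Born radii), and — when
    ``include_nonpolar`` — slope·(residue SAS in complex − residue SAS in
    the free receptor), the residue's share of the surface-burial term.
    The residue terms sum exactly to the corresponding totals.  A residue
    is a hotspot when its total is at or below the configured cutoff
    (default −1.0 kcal/mol).
    """
    cfg = config or SolvationConfig()
    frames = _as_frames(snapshots)
    if not frames:
        raise ValueError("need at least one snapshot")
    f0 = frames[0]
    ff.check_covers(f0)
    idx_r = select_atoms(f0, receptor_sel)
    idx_l = select_atoms(f0, ligand_sel)
    if idx_r.size == 0 or idx_l.size == 0:
        raise ValueError("receptor and ligand selections must be nonempty")
    idx_c = np.sort(np.concatenate([idx_r, idx_l]))

    # group receptor atoms by residue
    keys = [
        (str(f0.chain_ids[i]), int(f0.residue_local_indices[i]), str(f0.residue_names[i]))
        for i in idx_r
    ]
    order: list[tuple[str, int, str]] = []
    groups: dict[tuple[str, int, str], list[int]] = {}
    for i, key in zip(idx_r, keys):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(int(i))

    per = {key: {"e_ele": [], "e_vdw": [], "g_polar": [], "g_nonpolar": []} for key in order}
    for frame in frames:
        sub_c = ff.subset(idx_c)
        born_c = np.full(frame.n_atoms, np.nan)
        born_c[idx_c] = effective_born_radii(
            frame.coords[idx_c], sub_c.gb_radius, sub_c.gb_screen
        )
        if include_nonpolar:
            sub_r = ff.subset(idx_r)
            sas_complex = np.zeros(frame.n_atoms)
            sas_complex[idx_c] = sasa(
                frame.coords[idx_c], sub_c.lj_radius, cfg.sasa_probe, cfg.sasa_points
            )
            sas_alone = np.zeros(frame.n_atoms)
            sas_alone[idx_r] = sasa(
                frame.coords[idx_r], sub_r.lj_radius, cfg.sasa_probe, cfg.sasa_points
            )
        for key in order:
            res_idx = np.asarray(groups[key], dtype=int)
            e_ele, e_vdw = mm_energy(frame, ff, res_idx, idx_l)
            g_pol = _gb_cross(frame.coords, ff.charges, born_c, res_idx, idx_l, cfg)
            per[key]["e_ele"].append(e_ele)
            per[key]["e_vdw"].append(e_vdw)
            per[key]["g_polar"].append(g_pol)
            if include_nonpolar:
                dn = cfg.nonpolar_slope * float(
                    sas_complex[res_idx].sum() - sas_alone[res_idx].sum()
                )
                per[key]["g_nonpolar"].append(dn)
            else:
                per[key]["g_nonpolar"].append(0.0)

    rows = []
    for key in order:
        chain, resid, resname = key
        comp = {c: float(np.mean(v)) for c, v in per[key].items()}
        total = sum(comp.values())
        rows.append(
            {
                "chain": chain,
                "resid": resid,
                "resname": resname,
                "e_ele": comp["e_ele"],
                "e_vdw": comp["e_vdw"],
                "g_polar": comp["g_polar"],
                "g_nonpolar": comp["g_nonpolar"],
                "total": total,
                "hotspot": total <= cfg.hotspot_cutoff,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PoseRanking:
    """Outcome of multi-dielectric pose comparison."""

    best: str
    order: list[str]
    dominant: bool
    table: pd.DataFrame


def rank_poses(
    pose_energies: Mapping[str, Mapping[float, "EnergyReport | float"]],
    metric: str = "complex",
) -> PoseRanking:
    """Rank binding poses across a lipid-dielectric grid.

    The best pose is the one whose free energy is smallest at *every*
    dielectric (dominance).  If no pose dominates, poses are ranked by the
    mean over the grid and a warning is emitted: a low value at a single
    dielectric does not by itself select a pose.  ``metric`` picks the
    complex free energy (default; robust against strained poses with
    spuriously good binding differences) or the binding ΔG (``"binding"``).
    """
    if len(pose_energies) < 2:
        raise ValueError("need at least two poses")
    grids = {name: tuple(sorted(vals.keys())) for name, vals in pose_energies.items()}
    grid0 = next(iter(grids.values()))
    if any(g != grid0 for g in grids.values()):
        raise ValueError("poses were evaluated on different dielectric grids")

    def value(rep) -> float:
        if isinstance(rep, EnergyReport):
            return rep.complex["G_total"] if metric == "complex" else rep.delta_total
        return float(rep)

    names = list(pose_energies)
    vals = {name: {eps: value(pose_energies[name][eps]) for eps in grid0} for name in names}
    dominant_poses = [
        p
        for p in names
        if all(vals[p][eps] <= min(vals[q][eps] for q in names) for eps in grid0)
    ]
    means = {p: float(np.mean([vals[p][eps] for eps in grid0])) for p in names}
    order = sorted(names, key=lambda p: (means[p], p))
    if dominant_poses:
        best = dominant_poses[0]
        dominant = True
        order = [best] + [p for p in order if p != best]
    else:
        best = order[0]
        dominant = False
        msg = "no pose dominates at every dielectric; ranking by grid mean"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
    table = pd.DataFrame(
        [{"pose": p, **{f"eps_{eps:g}": vals[p][eps] for eps in grid0}, "mean": means[p]} for p in order]
    )
    return PoseRanking(best=best, order=order, dominant=dominant, table=table)


def subsample_snapshots(
    snapshots: "Trajectory | int", target: int
) -> "Trajectory | np.ndarray":
    """Evenly spaced snapshot subset: indices floor((i + 0.5)·N/n), i = 0..n−1.

    This is the rule that thins a 1350-snapshot analysis set to the
    135-snapshot binding-energy set with constant spacing and no
    duplicates.  Given an integer N the indices are returned; given a
    Trajectory the selected sub-trajectory is returned.
    """
    n_avail = snapshots.n_frames if isinstance(snapshots, Trajectory) else int(snapshots)
    if target < 1:
        raise ValueError("target must be >= 1")
    if target > n_avail:
        raise ValueError(f"target {target} exceeds available {n_avail}")
    idx = np.floor((np.arange(target) + 0.5) * n_avail / target).astype(int)
    if isinstance(snapshots, Trajectory):
        return Trajectory([snapshots.frames[i] for i in idx])
    return idx
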