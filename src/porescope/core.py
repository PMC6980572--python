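"""Core domain types and structure/trajectory I/O.

Conventions used throughout the package:

* coordinates are in Å, times in ns, energies in kcal/mol;
* residue numbering is 1-based and local to a chain; the pentamer's global
  numbering is sequential across chains in chain order (chain k, local i
  maps to global (k-1)*chain_length + i), so the five symmetry-equivalent
  lysines of a 5x136 channel carry global indices 106, 242, 378, 514, 650;
* a :class:`StructureFrame` stores its atom roster as flat numpy arrays;
  :class:`AtomRecord` is a per-atom view used at API boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureFrame",
    "Trajectory",
    "SubunitMap",
    "Selection",
    "MAINCHAIN_ATOMS",
    "LIGAND_RESNAMES",
    "parse_selection",
    "select_atoms",
    "read_structure",
    "write_structure",
    "ParseError",
    "RosterError",
]

#: Atom names forming the peptide mainchain (the ``mainchain`` selection class).
MAINCHAIN_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Residue names treated as ligand by the ``ligand`` selection class.
LIGAND_RESNAMES = frozenset({"LIG", "DHS", "K05", "01A"})


class ParseError(ValueError):
    """A structure file violated its format; the message names the line."""


class RosterError(ValueError):
    """Frames of one trajectory disagree on the atom roster."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: labels plus Cartesian coordinates in Å."""

    atom_name: str
    element: str
    chain_id: str
    residue_local_index: int
    residue_name: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        if self.residue_local_index < 1:
            raise ValueError("residue_local_index must be >= 1")
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)


class StructureFrame:
    """One conformation: an ordered atom roster with coordinates.

    Parameters
    ----------
    atoms
        Ordered atom records, or ``None`` when the array form is given.
    time_ns
        Timestamp of the frame (non-negative, ns).
    box
        Optional orthorhombic box lengths in Å.
    """

    __slots__ = (
        "atom_names",
        "elements",
        "chain_ids",
        "residue_local_indices",
        "residue_names",
        "coords",
        "time_ns",
        "box",
    )

    def __init__(
        self,
        atoms: Iterable[AtomRecord] | None = None,
        time_ns: float = 0.0,
        box: Sequence[float] | None = None,
        *,
        atom_names: np.ndarray | None = None,
        elements: np.ndarray | None = None,
        chain_ids: np.ndarray | None = None,
        residue_local_indices: np.ndarray | None = None,
        residue_names: np.ndarray | None = None,
        coords: np.ndarray | None = None,
    ) -> None:
        if atoms is not None:
            atoms = list(atoms)
            atom_names = np.array([a.atom_name for a in atoms], dtype=object)
            elements = np.array([a.element for a in atoms], dtype=object)
            chain_ids = np.array([a.chain_id for a in atoms], dtype=object)
            residue_local_indices = np.array(
                [a.residue_local_index for a in atoms], dtype=int
            )
            residue_names = np.array([a.residue_name for a in atoms], dtype=object)
            coords = (
                np.array([a.coords for a in atoms], dtype=float)
                if atoms
                else np.zeros((0, 3))
            )
        if coords is None:
            raise ValueError("either atoms or the array form must be given")
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        if time_ns < 0:
            raise ValueError("time_ns must be non-negative")
        if np.any(residue_local_indices < 1):
            raise ValueError("residue_local_index must be >= 1")
        self.atom_names = atom_names
        self.elements = elements
        self.chain_ids = chain_ids
        self.residue_local_indices = residue_local_indices
        self.residue_names = residue_names
        self.coords = coords
        self.time_ns = float(time_ns)
        self.box = None if box is None else np.asarray(box, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def atoms(self) -> list[AtomRecord]:
        return [self.atom(i) for i in range(self.n_atoms)]

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            atom_name=str(self.atom_names[i]),
            element=str(self.elements[i]),
            chain_id=str(self.chain_ids[i]),
            residue_local_index=int(self.residue_local_indices[i]),
            residue_name=str(self.residue_names[i]),
            coords=self.coords[i].copy(),
        )

    def roster_key(self) -> tuple:
        """Hashable roster identity (labels only, no coordinates)."""
        return (
            tuple(self.atom_names),
            tuple(self.elements),
            tuple(self.chain_ids),
            tuple(int(i) for i in self.residue_local_indices),
            tuple(self.residue_names),
        )

    def with_coords(self, coords: np.ndarray, time_ns: float | None = None) -> "StructureFrame":
        """Copy of this frame with new coordinates (labels shared)."""
        return StructureFrame(
            atom_names=self.atom_names,
            elements=self.elements,
            chain_ids=self.chain_ids,
            residue_local_indices=self.residue_local_indices,
            residue_names=self.residue_names,
            coords=np.asarray(coords, dtype=float),
            time_ns=self.time_ns if time_ns is None else time_ns,
            box=self.box,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<StructureFrame {self.n_atoms} atoms, t={self.time_ns:g} ns>"


class Trajectory:
    """Time-ordered sequence of frames sharing one atom roster."""

    def __init__(self, frames: Sequence[StructureFrame]):
        frames = list(frames)
        if not frames:
            raise ValueError("a Trajectory needs at least one frame")
        key0 = frames[0].roster_key()
        for k, f in enumerate(frames[1:], start=1):
            if f.roster_key() != key0:
                raise RosterError(f"frame {k} does not share the atom roster of frame 0")
        times = np.array([f.time_ns for f in frames], dtype=float)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame timestamps must be strictly increasing")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_ns(self) -> np.ndarray:
        return np.array([f.time_ns for f in self.frames], dtype=float)

    def __iter__(self) -> Iterator[StructureFrame]:
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.frames[i])
        return self.frames[i]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Trajectory {self.n_frames} frames x {self.frames[0].n_atoms} atoms>"


@dataclass(frozen=True)
class SubunitMap:
    """Bijection between global residue indices and (chain, local) pairs.

    The pentameric channel numbers its residues sequentially across chains:
    global = (chain_ordinal - 1) * chain_length + local.  With the default
    5 x 136 map the pore-lining lysine at local position 106 appears at
    global indices 106, 242, 378, 514 and 650.
    """

    n_chains: int = 5
    chain_length: int = 136

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.chain_length < 1:
            raise ValueError("n_chains and chain_length must be positive")

    @property
    def n_residues(self) -> int:
        return self.n_chains * self.chain_length

    def resolve_global_residue(self, chain_ordinal: int, local: int) -> int:
        """Global sequential index of residue ``local`` in chain ``chain_ordinal`` (both 1-based)."""
        if not 1 <= chain_ordinal <= self.n_chains:
            raise ValueError(f"chain_ordinal {chain_ordinal} outside 1..{self.n_chains}")
        if not 1 <= local <= self.chain_length:
            raise ValueError(f"local index {local} outside 1..{self.chain_length}")
        return (chain_ordinal - 1) * self.chain_length + local

    def resolve_local_residue(self, global_index: int) -> tuple[int, int]:
        """Inverse of :meth:`resolve_global_residue`."""
        if not 1 <= global_index <= self.n_residues:
            raise ValueError(f"global index {global_index} outside 1..{self.n_residues}")
        chain_ordinal = (global_index - 1) // self.chain_length + 1
        local = (global_index - 1) % self.chain_length + 1
        return chain_ordinal, local

    def equivalent_globals(self, local: int) -> list[int]:
        """Global indices of the symmetry-equivalent residues at one local position."""
        return [self.resolve_global_residue(c, local) for c in range(1, self.n_chains + 1)]


# ---------------------------------------------------------------------------
# Atom selections
# ---------------------------------------------------------------------------

_CLASSES = ("mainchain", "heavy", "ligand", "all")


@dataclass(frozen=True)
class Selection:
    """Predicate over atoms, conjunctive across the populated fields.

    ``chains``, ``residue_range`` (inclusive local-index bounds), ``residues``
    (explicit local indices), ``atom_names`` and ``klass`` are ANDed; ``None``
    fields do not constrain.  Evaluating a Selection depends only on the atom
    roster, so it yields the same index set on every frame of a trajectory.
    """

    chains: frozenset[str] | None = None
    residue_range: tuple[int, int] | None = None
    residues: frozenset[int] | None = None
    atom_names: frozenset[str] | None = None
    klass: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.klass is not None and self.klass not in _CLASSES:
            raise ValueError(f"unknown selection class {self.klass!r}")

    def mask(self, frame: StructureFrame) -> np.ndarray:
        m = np.ones(frame.n_atoms, dtype=bool)
        if self.chains is not None:
            m &= np.isin(frame.chain_ids, list(self.chains))
        if self.residue_range is not None:
            lo, hi = self.residue_range
            idx = frame.residue_local_indices
            m &= (idx >= lo) & (idx <= hi)
        if self.residues is not None:
            m &= np.isin(frame.residue_local_indices, list(self.residues))
        if self.atom_names is not None:
            m &= np.isin(frame.atom_names, list(self.atom_names))
        if self.klass == "mainchain":
            m &= np.isin(frame.atom_names, list(MAINCHAIN_ATOMS))
        elif self.klass == "heavy":
            m &= frame.elements != "H"
        elif self.klass == "ligand":
            m &= np.isin(frame.residue_names, list(LIGAND_RESNAMES))
        return m

    def __str__(self) -> str:
        return self.label or "<selection>"


_SEL_TOKEN = re.compile(r"\s+and\s+")


def parse_selection(text: str) -> Selection:
    """Parse the selection mini-language.

    Grammar: clauses joined by ``and``; each clause is one of
    ``chain A[,B...]``, ``resid 10-40`` or ``resid 5,9,12``,
    ``name CA[,N...]``, ``mainchain``, ``heavy``, ``ligand``, ``all``.
    """
    chains = residues = names = None
    rng = None
    klass = None
    for clause in _SEL_TOKEN.split(text.strip()):
        clause = clause.strip()
        if not clause:
            continue
        low = clause.lower()
        if low in _CLASSES:
            if klass is not None and klass != low:
                raise ValueError(f"conflicting selection classes in {text!r}")
            klass = low
        elif low.startswith("chain "):
            chains = frozenset(c.strip() for c in clause[6:].split(",") if c.strip())
        elif low.startswith("resid "):
            body = clause[6:].strip()
            if "-" in body and "," not in body:
                lo, hi = body.split("-")
                rng = (int(lo), int(hi))
            else:
                residues = frozenset(int(x) for x in body.split(",") if x.strip())
        elif low.startswith("name "):
            names = frozenset(n.strip() for n in clause[5:].split(",") if n.strip())
        else:
            raise ValueError(f"cannot parse selection clause {clause!r}")
    return Selection(
        chains=chains,
        residue_range=rng,
        residues=residues,
        atom_names=names,
        klass=None if klass == "all" else klass,
        label=text.strip(),
    )


def as_selection(sel: "Selection | str") -> Selection:
    return parse_selection(sel) if isinstance(sel, str) else sel


def select_atoms(frame: StructureFrame, sel: "Selection | str") -> np.ndarray:
    """Ordered atom indices of ``frame`` matching ``sel`` (possibly empty)."""
    return np.flatnonzero(as_selection(sel).mask(frame))


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column v3.3; MODEL/ENDMDL delimit frames)
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"TIME_NS\s+([-+0-9.eE]+)")


def _parse_pdb_atom(line: str, lineno: int) -> AtomRecord:
    if len(line) < 54:
        raise ParseError(f"line {lineno}: ATOM record shorter than coordinate fields")
    try:
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed ATOM record ({exc})") from None
    if altloc not in (" ", "A"):
        raise ParseError(f"line {lineno}: unsupported altloc {altloc!r}")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = re.sub(r"[^A-Za-z]", "", name)[:1].upper()
    return AtomRecord(
        atom_name=name,
        element=element,
        chain_id=chain,
        residue_local_index=resseq,
        residue_name=resname,
        coords=np.array([x, y, z]),
    )


def _read_pdb(path: Path) -> Trajectory:
    frames: list[StructureFrame] = []
    current: list[AtomRecord] = []
    time_ns: float | None = None
    in_model = False
    saw_model = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6]
            if rec == "MODEL ":
                if in_model:
                    raise ParseError(f"line {lineno}: nested MODEL")
                in_model = True
                saw_model = True
                current = []
            elif rec == "ENDMDL":
                if not in_model:
                    raise ParseError(f"line {lineno}: ENDMDL without MODEL")
                in_model = False
                t = time_ns if time_ns is not None else float(len(frames))
                frames.append(StructureFrame(current, time_ns=t))
                time_ns = None
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_pdb_atom(raw.rstrip("\n"), lineno))
            elif raw.startswith("REMARK"):
                m = _TIME_RE.search(raw)
                if m:
                    time_ns = float(m.group(1))
    if in_model:
        raise ParseError("unterminated MODEL block at end of file")
    if not saw_model:
        if not current:
            raise ParseError("no ATOM records found")
        frames.append(StructureFrame(current, time_ns=time_ns or 0.0))
    try:
        return Trajectory(frames)
    except RosterError as exc:
        raise RosterError(f"inconsistent atom roster across models: {exc}") from None


def _format_pdb_name(name: str) -> str:
    # PDB v3.3: atom names of <=3 chars start in column 14
    return f" {name:<3s}" if len(name) < 4 else name[:4]


def _write_pdb(traj: Trajectory, path: Path) -> None:
    multi = traj.n_frames > 1
    with open(path, "w") as fh:
        for imodel, frame in enumerate(traj.frames, start=1):
            fh.write(f"REMARK   6 TIME_NS {frame.time_ns:.6f}\n")
            if multi:
                fh.write(f"MODEL     {imodel:>4d}\n")
            for i in range(frame.n_atoms):
                serial = (i % 99999) + 1
                fh.write(
                    "ATOM  {serial:>5d} {name} {res:<3s} {chain}{resseq:>4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                        serial=serial,
                        name=_format_pdb_name(str(frame.atom_names[i])),
                        res=str(frame.residue_names[i])[:3],
                        chain=str(frame.chain_ids[i])[:1],
                        resseq=int(frame.residue_local_indices[i]) % 10000,
                        x=frame.coords[i, 0],
                        y=frame.coords[i, 1],
                        z=frame.coords[i, 2],
                        occ=1.0,
                        b=0.0,
                        el=str(frame.elements[i])[:2],
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# XYZ I/O (count line; comment line carrying "t=<ns>"; element x y z)
# ---------------------------------------------------------------------------


def _read_xyz(path: Path) -> Trajectory:
    frames: list[StructureFrame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected atom count") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = re.search(r"t=([-+0-9.eE]+)", comment)
        t = float(m.group(1)) if m else float(len(frames))
        atoms = []
        for k in range(n):
            lineno = i + 2 + k
            if lineno >= len(lines):
                raise ParseError(f"line {lineno + 1}: truncated XYZ block")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(f"line {lineno + 1}: expected 'element x y z'")
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise ParseError(f"line {lineno + 1}: non-numeric coordinate") from None
            atoms.append(
                AtomRecord(
                    atom_name=parts[0],
                    element=parts[0],
                    chain_id="A",
                    residue_local_index=k + 1,
                    residue_name="XYZ",
                    coords=np.array(xyz),
                )
            )
        frames.append(StructureFrame(atoms, time_ns=t))
        i += 2 + n
    if not frames:
        raise ParseError("empty XYZ file")
    return Trajectory(frames)


def _write_xyz(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"{frame.n_atoms}\n")
            fh.write(f"t={frame.time_ns:.6f}\n")
            for i in range(frame.n_atoms):
                x, y, z = frame.coords[i]
                fh.write(f"{frame.elements[i]} {x:.6f} {y:.6f} {z:.6f}\n")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pdb", "xyz"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_structure(path: str | Path, format: str | None = None) -> Trajectory:
    """Read a PDB (single- or multi-model) or XYZ file into a Trajectory."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_structure(
    traj: "Trajectory | StructureFrame", path: str | Path, format: str | None = None
) -> None:
    """Write a Trajectory (or single frame) as PDB or XYZ."""
    if isinstance(traj, StructureFrame):
        traj = Trajectory([traj])
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        _write_pdb(traj, path)
    elif fmt == "xyz":
        _write_xyz(traj, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
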