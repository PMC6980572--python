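import numpy as np
import pytest

from porescope.core import AtomRecord, StructureFrame
from porescope.energetics import SolvationConfig
from porescope.synth import PentamerSpec, add_ligand, build_ideal_pentamer, make_toy_ff


@pytest.fixture(scope="session")
def small_pentamer():
    """Ideal 5x20 pentamer with mainchain pseudo-residues, constant ring radius 8 Å."""
    return build_ideal_pentamer(
        PentamerSpec(chain_length=20, radius=8.0, atoms_per_residue=4)
    )


@pytest.fixture(scope="session")
def full_pentamer():
    """Ideal 5x136 single-site pentamer (the full-size subunit map)."""
    return build_ideal_pentamer(PentamerSpec(chain_length=136, radius=8.0))


@pytest.fixture(scope="session")
def complex_fixture():
    """Small pentamer with a polar ring ligand docked above the pore mouth."""
    receptor = build_ideal_pentamer(
        PentamerSpec(chain_length=8, radius=6.0, atoms_per_residue=4)
    )
    frame = add_ligand(receptor, center=(0.0, 0.0, 6.0), seed=0)
    ff = make_toy_ff(frame, "pentamer_ligand", seed=0)
    return frame, ff


@pytest.fixture(scope="session")
def fast_solv():
    """Solvation config with a light SASA quadrature for test speed."""
    return SolvationConfig(sasa_points=240)


def make_frame(coords, names=None, elements=None, resids=None, chains=None, resnames=None):
    """Ad-hoc frame builder for small numeric fixtures."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    atoms = [
        AtomRecord(
            atom_name=(names or ["X"] * n)[i],
            element=(elements or ["C"] * n)[i],
            chain_id=(chains or ["A"] * n)[i],
            residue_local_index=(resids or list(range(1, n + 1)))[i],
            residue_name=(resnames or ["UNK"] * n)[i],
            coords=coords[i],
        )
        for i in range(n)
    ]
    return StructureFrame(atoms)
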