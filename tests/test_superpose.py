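"""Kabsch superposition, dual-mode RMSD, symmetry correction and series analytics."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from porescope.core import StructureFrame, Trajectory
from porescope.superpose import (
    AutomorphismBudgetError,
    DegenerateFitError,
    RmsdSeries,
    equilibrium_onset,
    kabsch,
    open_state_persistence,
    rmsd_series,
    segment_clusters,
    symmetry_corrected_rmsd,
)
from porescope.synth import PentamerSpec, add_ligand, build_ideal_pentamer

from conftest import make_frame


def _rand_points(n, seed):
    return np.random.default_rng(seed).normal(size=(n, 3))


class TestKabsch:
    def test_identity(self):
        P = _rand_points(10, 0)
        T, r = kabsch(P, P)
        assert r < 1e-12
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_transform(self):
        P = _rand_points(25, 1)
        R = Rotation.from_euler("zyx", [40, -25, 110], degrees=True).as_matrix()
        t = np.array([3.0, -7.0, 2.5])
        Q = P @ R.T + t
        T, r = kabsch(P, Q)
        assert r < 1e-9
        np.testing.assert_allclose(T.rotation, R, atol=1e-9)
        np.testing.assert_allclose(T.translation, t, atol=1e-9)
        np.testing.assert_allclose(T.inverse().apply(Q), P, atol=1e-9)

    def test_matches_scipy_align_vectors(self):
        """Independent oracle: scipy's optimal alignment gives the same residual."""
        P, Q = _rand_points(15, 2), _rand_points(15, 3)
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        rot, _ = Rotation.align_vectors(Qc, Pc)
        oracle = np.sqrt(np.mean(np.sum((Pc @ rot.as_matrix().T - Qc) ** 2, axis=1)))
        _, r = kabsch(P, Q)
        assert r == pytest.approx(oracle, abs=1e-9)

    def test_mirror_image_keeps_proper_rotation(self):
        P = _rand_points(12, 4)
        Q = P.copy()
        Q[:, 0] *= -1  # reflection: not reachable by a proper rotation
        T, r = kabsch(P, Q)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)
        assert r > 0.1

    @pytest.mark.parametrize(
        "pts",
        [
            np.zeros((2, 3)),
            np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),
        ],
    )
    def test_degenerate_fit_rejected(self, pts):
        with pytest.raises(DegenerateFitError):
            kabsch(pts, pts + 1.0)


class TestRmsdSeries:
    @pytest.fixture()
    def ligand_shift_traj(self):
        receptor = build_ideal_pentamer(
            PentamerSpec(chain_length=6, radius=6.0, atoms_per_residue=4)
        )
        f0 = add_ligand(receptor, center=(0.0, 0.0, 5.0), seed=1)
        shifted = f0.coords.copy()
        lig = np.flatnonzero(f0.residue_names == "LIG")
        shifted[lig] += np.array([0.0, 0.0, 5.0])
        f1 = f0.with_coords(shifted, time_ns=1.0)
        return Trajectory([f0, f1])

    def test_rigid_motion_gives_zero_ls_fit(self, small_pentamer):
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        frames = [small_pentamer]
        for k in range(1, 4):
            frames.append(
                small_pentamer.with_coords(
                    small_pentamer.coords @ np.linalg.matrix_power(R, k).T + k,
                    time_ns=float(k),
                )
            )
        s = rmsd_series(Trajectory(frames), fit_sel="mainchain", mode="ls_fit")
        np.testing.assert_allclose(s.rmsd, 0.0, atol=1e-9)

    def test_translated_ligand_exact_values(self, ligand_shift_traj):
        """+5 Å ligand shift: No-Fit and protein-fitted RMSD are 5.0; ligand-fitted is 0."""
        no_fit = rmsd_series(
            ligand_shift_traj, fit_sel="mainchain", measure_sel="ligand", mode="no_fit"
        )
        assert no_fit.rmsd[1] == pytest.approx(5.0, abs=1e-9)
        ls_protein = rmsd_series(
            ligand_shift_traj, fit_sel="mainchain", measure_sel="ligand", mode="ls_fit"
        )
        assert ls_protein.rmsd[1] == pytest.approx(5.0, abs=1e-9)
        ls_ligand = rmsd_series(ligand_shift_traj, fit_sel="ligand", mode="ls_fit")
        assert ls_ligand.rmsd[1] == pytest.approx(0.0, abs=1e-9)

    def test_ls_fit_never_exceeds_no_fit(self, small_pentamer):
        rng = np.random.default_rng(8)
        frames = [small_pentamer]
        for k in range(1, 6):
            frames.append(
                small_pentamer.with_coords(
                    small_pentamer.coords + rng.normal(0, 0.8, small_pentamer.coords.shape),
                    time_ns=float(k),
                )
            )
        traj = Trajectory(frames)
        meas = "chain A and heavy"
        ls = rmsd_series(traj, fit_sel=meas, measure_sel=meas, mode="ls_fit")
        nf = rmsd_series(traj, fit_sel="mainchain", measure_sel=meas, mode="no_fit")
        assert np.all(ls.rmsd <= nf.rmsd + 1e-12)

    def test_empty_selection_rejected(self, small_pentamer):
        traj = Trajectory([small_pentamer])
        with pytest.raises(ValueError):
            rmsd_series(traj, fit_sel="chain Z")


def nitro_fixture():
    """Anchored nitro-like group: the only nontrivial automorphism swaps the oxygens."""
    G = nx.Graph()
    elements = ["C", "N", "O", "O", "F"]
    for i, el in enumerate(elements):
        G.add_node(i, element=el)
    G.add_edges_from([(0, 1), (1, 2), (1, 3), (0, 4)])
    ref = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.4, 0.0, 0.0],
            [2.1, 1.0, 0.0],
            [2.1, -1.0, 0.0],
            [-0.7, 0.2, 0.9],  # off-plane anchor pins the orientation
        ]
    )
    return ref, G


class TestSymmetryRmsd:
    def test_swapped_nitro_oxygens(self):
        ref, G = nitro_fixture()
        mob = ref[[0, 1, 3, 2, 4]]
        out = symmetry_corrected_rmsd(mob, ref, G)
        assert out.naive > 0.1
        assert out.corrected == pytest.approx(0.0, abs=1e-9)
        assert out.n_automorphisms == 2

    def test_asymmetric_molecule_unchanged(self):
        coords = _rand_points(5, 6)
        G = nx.Graph()
        for i, el in enumerate(["C", "N", "O", "S", "P"]):
            G.add_node(i, element=el)
        G.add_edges_from([(0, 1), (1, 2), (2, 3), (3, 4)])
        out = symmetry_corrected_rmsd(coords + 0.3, coords, G)
        assert out.corrected == pytest.approx(out.naive, abs=1e-12)
        assert out.n_automorphisms == 1

    def test_ring_matches_exhaustive_permutation_oracle(self):
        """Hexagonal ring (12 automorphisms) against brute-force enumeration."""
        G = nx.Graph()
        for i in range(6):
            G.add_node(i, element="C")
        edges = [(i, (i + 1) % 6) for i in range(6)]
        G.add_edges_from(edges)
        ang = np.arange(6) * np.pi / 3
        ref = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
        mob = ref + _rand_points(6, 7) * 0.2
        out = symmetry_corrected_rmsd(mob, ref, G)
        assert out.n_automorphisms == 12
        adj = set(map(frozenset, edges))
        best = np.inf
        for perm in itertools.permutations(range(6)):
            if all(frozenset((perm[a], perm[b])) in adj for a, b in edges):
                _, r = kabsch(mob[list(perm)], ref)
                best = min(best, r)
        assert out.corrected == pytest.approx(best, abs=1e-12)

    def test_automorphism_budget(self):
        ref, G = nitro_fixture()
        with pytest.raises(AutomorphismBudgetError):
            symmetry_corrected_rmsd(ref, ref, G, max_automorphisms=1)

    def test_corrected_never_exceeds_naive(self):
        ref, G = nitro_fixture()
        rng = np.random.default_rng(12)
        for _ in range(5):
            mob = ref + rng.normal(0, 0.5, ref.shape)
            out = symmetry_corrected_rmsd(mob, ref, G)
            assert out.corrected <= out.naive + 1e-12


def _series(t, x):
    return RmsdSeries("ls_fit", "fit", "fit", np.asarray(t, float), np.asarray(x, float))


class TestEquilibriumOnset:
    def test_constant_series_onset_at_start(self):
        t = np.arange(0.0, 40.0, 0.5)
        assert equilibrium_onset(_series(t, np.full(t.size, 1.5)), 10.0, 1.0) == 0.0

    def test_ramp_then_flat_matches_brute_force(self):
        t = np.arange(0.0, 160.0, 0.5)
        x = np.where(t < 20.0, t * 3.0 / 20.0, 3.0)
        s = _series(t, x)
        window, band = 10.0, 0.5

        def oracle():
            starts = [i for i in range(t.size) if t[i] + window <= t[-1] + 1e-12]
            def ok(i):
                w = x[(t >= t[i]) & (t <= t[i] + window + 1e-12)]
                return w.max() - w.min() <= band
            for k, i in enumerate(starts):
                if all(ok(j) for j in starts[k:]):
                    return t[i]
            return None

        assert equilibrium_onset(s, window, band) == pytest.approx(oracle())
        # as the band shrinks the onset approaches the end of the ramp (20 ns)
        assert equilibrium_onset(s, window, 1e-9) == pytest.approx(20.0)

    def test_unbounded_ramp_never_settles(self):
        t = np.arange(0.0, 100.0, 0.5)
        assert equilibrium_onset(_series(t, 0.15 * t), 10.0, 1.0) is None

    def test_short_series_rejected(self):
        t = np.arange(0.0, 15.0, 0.5)
        with pytest.raises(ValueError):
            equilibrium_onset(_series(t, np.zeros(t.size)), 10.0, 1.0)


class TestClusterSegmentation:
    def test_flat_series_single_cluster(self):
        t = np.arange(20.0, 155.5, 0.5)
        seg = segment_clusters(_series(t, np.full(t.size, 2.0)), 10.0, 1.5)
        assert seg.n_clusters == 1
        assert seg.boundaries_ns == [20.0, 155.0]

    def test_step_series_two_clusters(self):
        """A 2→5 Å step at 115 ns over [20,155] splits at {20, 115, 155}."""
        t = np.arange(20.0, 155.5, 0.5)
        x = np.where(t < 115.0, 2.0, 5.0)
        seg = segment_clusters(_series(t, x), 10.0, 1.5)
        assert seg.boundaries_ns == [20.0, 115.0, 155.0]
        assert seg.mean_rmsd == pytest.approx([2.0, 5.0])

    def test_jump_above_any_step_single_cluster(self):
        t = np.arange(20.0, 155.5, 0.5)
        x = np.where(t < 115.0, 2.0, 5.0)
        assert segment_clusters(_series(t, x), 10.0, 10.0).n_clusters == 1

    def test_medoid_tie_breaks_earliest(self):
        t = np.arange(0.0, 30.0, 1.0)
        x = np.full(t.size, 1.0)
        seg = segment_clusters(_series(t, x), 5.0, 1.0)
        assert seg.representatives == [0]


class TestOpenStatePersistence:
    def test_open_for_80_ns_then_lost(self):
        """Below the 3.0 Å threshold for 80 ns, then RMSD keeps increasing."""
        t = np.arange(0.0, 110.5, 0.5)
        x = np.where(t <= 80.0, 1.0 + 0.5 * np.sin(t / 7.0), 3.2 + 0.02 * (t - 80.0))
        x[0] = 0.0
        res = open_state_persistence(_series(t, x), threshold=3.0)
        assert res.duration_ns == pytest.approx(80.0)
        assert not res.censored

    def test_never_lost_is_censored(self):
        t = np.arange(0.0, 110.5, 0.5)
        res = open_state_persistence(_series(t, np.full(t.size, 1.2)), 3.0)
        assert res.censored and res.duration_ns == pytest.approx(110.0)

    def test_spike_that_recovers_does_not_end_state(self):
        t = np.arange(0.0, 50.5, 0.5)
        x = np.full(t.size, 1.0)
        x[40] = 4.0  # single-frame excursion
        res = open_state_persistence(_series(t, x), 3.0)
        assert res.censored

    def test_zero_threshold_zero_duration(self):
        t = np.arange(0.0, 50.5, 0.5)
        x = np.abs(np.random.default_rng(3).normal(0.5, 0.1, t.size))
        x[0] = 0.0
        res = open_state_persistence(_series(t, x), threshold=0.0)
        assert res.duration_ns == 0.0
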