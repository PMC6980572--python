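"""MM terms, Hawkins GB, SASA, binding free energy, decomposition, pose ranking."""

import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from porescope.core import Trajectory, select_atoms
from porescope.energetics import (
    COULOMB_K,
    ForceFieldTable,
    SolvationConfig,
    _gb_cross,
    binding_free_energy,
    effective_born_radii,
    gb_polar,
    membrane_offset,
    mm_energy,
    nonpolar_energy,
    rank_poses,
    residue_decomposition,
    sasa,
    subsample_snapshots,
)
from porescope.synth import (
    LipidSlabSpec,
    PentamerSpec,
    add_ligand,
    build_ideal_pentamer,
    build_lipid_slab,
    make_toy_ff,
)

from conftest import make_frame


def uniform_ff(n, q=0.0, lj_r=1.7, lj_e=0.1, gb_r=1.5):
    return ForceFieldTable(
        charges=np.full(n, float(q)),
        lj_radius=np.full(n, lj_r),
        lj_eps=np.full(n, lj_e),
        gb_radius=np.full(n, gb_r),
    )


class TestMMEnergy:
    def test_coulomb_worked_value(self):
        """Two unit charges at k/100 Å give exactly +100 kcal/mol."""
        frame = make_frame([[0, 0, 0], [COULOMB_K / 100.0, 0, 0]])
        ff = uniform_ff(2, q=1.0, lj_e=0.0)
        e_ele, e_vdw = mm_energy(frame, ff)
        assert e_ele == pytest.approx(100.0, abs=1e-9)
        assert e_vdw == 0.0

    def test_lj_minimum_depth(self):
        frame = make_frame([[0, 0, 0], [3.4, 0, 0]])  # rmin = 1.7 + 1.7
        ff = uniform_ff(2, q=0.0, lj_e=0.25)
        _, e_vdw = mm_energy(frame, ff)
        assert e_vdw == pytest.approx(-0.25, abs=1e-12)

    def test_random_cluster_matches_brute_force(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 12, (20, 3))
        frame = make_frame(coords)
        ff = ForceFieldTable(
            charges=rng.uniform(-0.5, 0.5, 20),
            lj_radius=rng.uniform(1.2, 2.0, 20),
            lj_eps=rng.uniform(0.05, 0.3, 20),
            gb_radius=np.full(20, 1.5),
        )
        e_ele, e_vdw = mm_energy(frame, ff)
        ref_ele = ref_vdw = 0.0
        for i in range(20):
            for j in range(i + 1, 20):
                r = np.linalg.norm(coords[i] - coords[j])
                ref_ele += COULOMB_K * ff.charges[i] * ff.charges[j] / r
                rmin = ff.lj_radius[i] + ff.lj_radius[j]
                eps = np.sqrt(ff.lj_eps[i] * ff.lj_eps[j])
                ref_vdw += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert e_ele == pytest.approx(ref_ele, abs=1e-12)
        assert e_vdw == pytest.approx(ref_vdw, abs=1e-10)

    def test_cross_group_excludes_intra_pairs(self):
        frame = make_frame([[0, 0, 0], [2, 0, 0], [10, 0, 0], [12, 0, 0]])
        ff = uniform_ff(4, q=0.3, lj_e=0.0)
        e_ab, _ = mm_energy(frame, ff, np.array([0, 1]), np.array([2, 3]))
        ref = sum(
            COULOMB_K * 0.09 / np.linalg.norm(frame.coords[i] - frame.coords[j])
            for i in (0, 1)
            for j in (2, 3)
        )
        assert e_ab == pytest.approx(ref, abs=1e-12)

    def test_overlapping_atoms_rejected(self):
        frame = make_frame([[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="overlap"):
            mm_energy(frame, uniform_ff(2))


class TestGeneralizedBorn:
    def test_isolated_ion_born_closed_form(self):
        """Single ion: Hawkins GB reduces exactly to the Born equation."""
        frame = make_frame([[0.0, 0.0, 0.0]])
        ff = make_toy_ff(frame, "born_ion")
        cfg = SolvationConfig(membrane=False)
        expected = -0.5 * COULOMB_K * (1.0 - 1.0 / 80.0) / 2.0
        assert gb_polar(frame, ff, cfg) == pytest.approx(expected, abs=1e-9)

    def test_matched_dielectrics_give_zero(self):
        frame = make_frame([[0.0, 0, 0], [3.0, 0, 0]])
        ff = uniform_ff(2, q=0.7)
        cfg = SolvationConfig(eps_internal=4.0, eps_lipid=4.0, membrane=True)
        assert gb_polar(frame, ff, cfg) == 0.0

    def test_distant_ions_born_plus_screened_coulomb(self):
        r = 1000.0
        frame = make_frame([[0, 0, 0], [r, 0, 0]])
        ff = ForceFieldTable(
            charges=[1.0, -1.0],
            lj_radius=[1.5, 1.5],
            lj_eps=[0.1, 0.1],
            gb_radius=[2.0, 1.5],
        )
        cfg = SolvationConfig(membrane=False)
        tau = 1.0 - 1.0 / 80.0
        expected = (
            -0.5 * COULOMB_K * tau * (1.0 / 2.0 + 1.0 / 1.5)
            - COULOMB_K * tau * (-1.0) / r
        )
        assert gb_polar(frame, ff, cfg) == pytest.approx(expected, abs=1e-6)

    def test_descreening_shrinks_born_radii(self):
        """A close neighbour displaces solvent and grows the effective radius."""
        coords = np.array([[0.0, 0, 0], [3.5, 0, 0]])
        R = effective_born_radii(coords, np.array([1.5, 1.5]), np.array([0.8, 0.8]))
        assert np.all(R > 1.5)
        far = effective_born_radii(
            np.array([[0.0, 0, 0], [500.0, 0, 0]]), np.array([1.5, 1.5]), np.array([0.8, 0.8])
        )
        np.testing.assert_allclose(far, 1.5, atol=1e-6)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        area = sasa(np.zeros((1, 3)), np.array([1.6]), probe=1.4)
        assert area[0] == pytest.approx(4 * np.pi * 3.0**2, rel=0.005)

    def test_distant_spheres_additive(self):
        area = sasa(np.array([[0.0, 0, 0], [100.0, 0, 0]]), np.array([1.6, 2.0]), probe=1.4)
        expect = 4 * np.pi * np.array([3.0**2, 3.4**2])
        np.testing.assert_allclose(area, expect, rtol=0.005)

    def test_caged_atom_fully_buried(self):
        """An atom surrounded by an icosahedral cage has zero accessible surface."""
        phi = (1 + np.sqrt(5)) / 2
        verts = np.array(
            [
                [0, s1, s2 * phi]
                for s1 in (-1, 1)
                for s2 in (-1, 1)
            ]
            + [[s1, s2 * phi, 0] for s1 in (-1, 1) for s2 in (-1, 1)]
            + [[s1 * phi, 0, s2] for s1 in (-1, 1) for s2 in (-1, 1)]
        )
        cage = 3.0 * verts / np.linalg.norm(verts[0])
        coords = np.vstack([[0.0, 0.0, 0.0], cage])
        radii = np.concatenate([[1.0], np.full(12, 2.6)])
        area = sasa(coords, radii, probe=1.4)
        assert area[0] == 0.0


class TestNonpolar:
    def test_zero_surface_gives_intercept(self):
        assert nonpolar_energy(0.0) == pytest.approx(0.92, abs=1e-12)

    def test_printed_slope(self):
        slope = (nonpolar_energy(1000.0) - nonpolar_energy(0.0)) / 1000.0
        assert slope == pytest.approx(0.0054, abs=1e-12)

    def test_worked_value(self):
        assert nonpolar_energy(100.0) == pytest.approx(1.46, abs=1e-12)

    def test_negative_surface_rejected(self):
        with pytest.raises(ValueError):
            nonpolar_energy(-1.0)


class TestMembraneOffset:
    def test_offset_sign_convention(self):
        """mctrdz = protein center z − lipid center z."""
        protein = build_ideal_pentamer(PentamerSpec(chain_length=4, radius=6.0))
        shifted = protein.with_coords(
            protein.coords + np.array([0.0, 0.0, 5.0 - protein.coords[:, 2].mean()])
        )
        slab = build_lipid_slab(LipidSlabSpec(center_z=3.0, n_sites=4000, seed=1))
        from porescope.core import StructureFrame

        both = StructureFrame(shifted.atoms + slab.atoms)
        off = membrane_offset(both, "chain A,B,C,D,E", "chain M")
        lipid_z = slab.coords[:, 2].mean()
        assert off == pytest.approx(5.0 - lipid_z, abs=1e-9)

    def test_identical_centers_zero(self):
        frame = make_frame(
            [[0, 0, 1.0], [0, 0, -1.0], [3, 0, 2.0], [3, 0, -2.0]],
            chains=["A", "A", "M", "M"],
        )
        assert membrane_offset(frame, "chain A", "chain M") == pytest.approx(0.0)

    def test_empty_selection_rejected(self):
        frame = make_frame([[0, 0, 0]], chains=["A"])
        with pytest.raises(ValueError):
            membrane_offset(frame, "chain A", "chain M")


class TestBindingFreeEnergy:
    def test_separated_ligand_noninteracting_limit(self, fast_solv):
        """With the ligand far away and the additive nonpolar form, ΔG → 0."""
        receptor = build_ideal_pentamer(
            PentamerSpec(chain_length=4, radius=6.0, atoms_per_residue=4)
        )
        frame = add_ligand(receptor, center=(0.0, 0.0, 500.0), seed=0)
        ff = make_toy_ff(frame, "pentamer_ligand", seed=0)
        cfg = SolvationConfig(membrane=False, nonpolar_intercept=0.0, sasa_points=240)
        rep = binding_free_energy([frame], "chain A,B,C,D,E", "ligand", ff, cfg)
        assert rep.delta_total == pytest.approx(0.0, abs=1e-4)

    def test_component_sum_is_total(self, complex_fixture, fast_solv):
        frame, ff = complex_fixture
        rep = binding_free_energy([frame], "chain A,B,C,D,E", "ligand", ff, fast_solv)
        for species in (rep.complex, rep.receptor, rep.ligand):
            assert species["G_total"] == pytest.approx(
                species["E_ele"] + species["E_vdw"] + species["G_polar"] + species["G_nonpolar"],
                abs=1e-9,
            )
        assert not rep.entropy_included

    def test_desolvation_penalty_monotone_in_lipid_dielectric(self, complex_fixture):
        """Raising ε_lip 1→2→4 lowers the desolvation penalty, so ΔG is nonincreasing."""
        frame, ff = complex_fixture
        values = []
        for eps in (1.0, 2.0, 4.0):
            cfg = SolvationConfig(eps_lipid=eps, membrane=True, sasa_points=240)
            rep = binding_free_energy([frame], "chain A,B,C,D,E", "ligand", ff, cfg)
            values.append(rep.delta_total)
        assert values[0] >= values[1] >= values[2]

    def test_rigid_transform_invariance(self, complex_fixture, fast_solv):
        """MM and GB terms are exactly rotation invariant; the quadrature SASA
        term only to its sampling tolerance."""
        frame, ff = complex_fixture
        rep1 = binding_free_energy([frame], "chain A,B,C,D,E", "ligand", ff, fast_solv)
        R = Rotation.from_euler("xyz", [15, 75, -40], degrees=True).as_matrix()
        moved = frame.with_coords(frame.coords @ R.T + np.array([4.0, 5.0, -6.0]))
        rep2 = binding_free_energy([moved], "chain A,B,C,D,E", "ligand", ff, fast_solv)
        for comp in ("E_ele", "E_vdw", "G_polar"):
            assert rep2.delta[comp] == pytest.approx(rep1.delta[comp], abs=1e-5)
        assert rep2.delta_total == pytest.approx(rep1.delta_total, abs=0.2)

    def test_mctrdz_recorded_per_snapshot(self, fast_solv):
        receptor = build_ideal_pentamer(PentamerSpec(chain_length=4, radius=6.0))
        frame = add_ligand(receptor, center=(0.0, 0.0, 8.0), seed=0)
        slab = build_lipid_slab(LipidSlabSpec(center_z=-2.0, n_sites=50, seed=2))
        from porescope.core import StructureFrame

        both = StructureFrame(frame.atoms + slab.atoms)
        ff = make_toy_ff(both, "pentamer_ligand", seed=0)
        rep = binding_free_energy(
            [both], "chain A,B,C,D,E", "ligand", ff, fast_solv, lipid_sel="chain M"
        )
        assert rep.mctrdz is not None and len(rep.mctrdz) == 1


class TestResidueDecomposition:
    def test_sums_to_pairwise_totals(self, complex_fixture, fast_solv):
        """Per-residue terms conserve the receptor–ligand interaction exactly."""
        frame, ff = complex_fixture
        dec = residue_decomposition([frame], "chain A,B,C,D,E", "ligand", ff, fast_solv)
        idx_r = select_atoms(frame, "chain A,B,C,D,E")
        idx_l = select_atoms(frame, "ligand")
        e_ele, e_vdw = mm_energy(frame, ff, idx_r, idx_l)
        assert dec["e_ele"].sum() == pytest.approx(e_ele, abs=1e-9)
        assert dec["e_vdw"].sum() == pytest.approx(e_vdw, abs=1e-9)
        idx_c = np.sort(np.concatenate([idx_r, idx_l]))
        sub = ff.subset(idx_c)
        born = np.full(frame.n_atoms, np.nan)
        born[idx_c] = effective_born_radii(
            frame.coords[idx_c], sub.gb_radius, sub.gb_screen
        )
        g_cross = _gb_cross(frame.coords, ff.charges, born, idx_r, idx_l, fast_solv)
        assert dec["g_polar"].sum() == pytest.approx(g_cross, abs=1e-9)
        np.testing.assert_allclose(
            dec["total"], dec[["e_ele", "e_vdw", "g_polar", "g_nonpolar"]].sum(axis=1)
        )

    def test_hotspot_threshold_semantics(self, complex_fixture, fast_solv):
        """Hotspot iff interaction ≤ −1.0 kcal/mol; −0.9 must not be flagged."""
        frame, ff = complex_fixture
        dec = residue_decomposition([frame], "chain A,B,C,D,E", "ligand", ff, fast_solv)
        np.testing.assert_array_equal(dec["hotspot"], dec["total"] <= -1.0)
        strict = SolvationConfig(hotspot_cutoff=-1e9, sasa_points=240)
        dec2 = residue_decomposition([frame], "chain A,B,C,D,E", "ligand", ff, strict)
        assert not dec2["hotspot"].any()

    def test_close_contact_residues_are_hotspots(self, fast_solv):
        """Residues packed against the ligand cross the −1 kcal/mol mark."""
        receptor = build_ideal_pentamer(
            PentamerSpec(chain_length=8, radius=4.0, atoms_per_residue=4)
        )
        frame = add_ligand(receptor, center=(0.0, 0.0, 6.0), radius=2.2, seed=1)
        ff = make_toy_ff(frame, "pentamer_ligand", seed=1)
        dec = residue_decomposition([frame], "chain A,B,C,D,E", "ligand", ff, fast_solv)
        assert dec["hotspot"].any()
        assert dec.loc[dec["hotspot"], "total"].max() <= -1.0


class TestRankPoses:
    def _reports(self, values):
        # values: pose -> {eps: complex total}
        return {
            pose: {eps: float(v) for eps, v in per.items()} for pose, per in values.items()
        }

    def test_dominant_pose_wins(self):
        r = self._reports(
            {"A": {1: -10, 2: -11, 4: -12}, "B": {1: -8, 2: -9, 4: -10}}
        )
        out = rank_poses(r)
        assert out.best == "A" and out.dominant

    def test_no_dominance_warns_and_ranks_by_mean(self):
        r = self._reports({"A": {1: -10, 4: -5}, "B": {1: -6, 4: -9}})
        with pytest.warns(UserWarning, match="dominat"):
            out = rank_poses(r)
        assert not out.dominant
        assert out.best == "A"  # mean -7.5 vs -7.5 ... tie broken by name

    def test_order_invariant_to_input_order(self):
        vals = {"p1": {1: -3, 4: -4}, "p2": {1: -5, 4: -6}, "p3": {1: -1, 4: -2}}
        a = rank_poses(self._reports(vals))
        b = rank_poses(self._reports(dict(reversed(list(vals.items())))))
        assert a.order == b.order and a.best == b.best

    def test_matches_brute_force_comparator(self):
        rng = np.random.default_rng(5)
        vals = {
            f"p{k}": {eps: float(rng.uniform(-12, -2)) for eps in (1, 2, 4)}
            for k in range(4)
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = rank_poses(self._reports(vals))
        means = {p: np.mean(list(v.values())) for p, v in vals.items()}
        assert out.order == sorted(vals, key=lambda p: (means[p], p))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            rank_poses(self._reports({"A": {1: -1, 2: -2}, "B": {1: -1, 4: -2}}))


class TestSubsampling:
    def test_documented_rule(self):
        np.testing.assert_array_equal(subsample_snapshots(10, 5), [1, 3, 5, 7, 9])

    def test_identity_when_target_equals_n(self):
        np.testing.assert_array_equal(subsample_snapshots(7, 7), np.arange(7))

    def test_study_scale_constant_spacing(self):
        """1350 recorded snapshots thin to 135 with constant spacing 10."""
        idx = subsample_snapshots(1350, 135)
        assert idx.size == 135 and np.unique(idx).size == 135
        assert np.all(np.diff(idx) == 10)

    def test_target_above_available_rejected(self):
        with pytest.raises(ValueError):
            subsample_snapshots(10, 11)

    def test_trajectory_form(self, small_pentamer):
        from porescope.synth import perturb_trajectory

        traj = perturb_trajectory(small_pentamer, 10, 0.1, seed=0)
        sub = subsample_snapshots(traj, 5)
        assert isinstance(sub, Trajectory) and sub.n_frames == 5
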