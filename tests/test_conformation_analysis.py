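"""Dihedrals, hydrogen bonds, secondary structure, quality checks and
cavity detection against constructed fixtures with known answers."""

import math

import numpy as np
import pytest

from foldkit.conformation_analysis import (
    BackboneGeometry,
    assign_secondary_structure,
    backbone_normality,
    cavity_volumes,
    chirality_check,
    compute_hbonds,
    dihedral,
    hbond_energy,
    packing_score,
    phi_psi,
    place_amide_hydrogen,
    quality_report,
    rama_log_density,
    ramachandran_score,
    ss_percentages,
    KS_COUPLING,
)
from foldkit.structure_io import group_residues
from foldkit.synthetic_fixtures import (
    BackboneSpec,
    build_backbone,
    helix_bundle,
    hollow_shell,
    ideal_helix,
    ideal_strand,
    mirror,
    random_coil,
    _place,
)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([1, 1, 0], [0, 0, 0], [2, 0, 0], [1, 1, 0] + np.array([1, 0, 0])) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        ang = dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0])
        assert abs(ang) == pytest.approx(180.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_mirroring_negates_angle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 5
        ang = dihedral(*pts)
        flipped = pts * np.array([-1.0, 1.0, 1.0])
        if abs(abs(ang) - 180.0) > 1e-6:
            assert dihedral(*flipped) == pytest.approx(-ang, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])


class TestPhiPsi:
    @pytest.mark.parametrize("angles", [(-57.0, -47.0), (-120.0, 130.0)])
    def test_round_trip_recovers_builder_angles(self, angles):
        phi, psi = angles
        model = build_backbone(BackboneSpec(np.full(12, phi), np.full(12, psi)))
        geom = phi_psi(model)
        np.testing.assert_allclose(geom.phi[1:], phi, atol=0.5)
        np.testing.assert_allclose(geom.psi[:-1], psi, atol=0.5)
        np.testing.assert_allclose(np.abs(geom.omega[1:]), 180.0, atol=0.5)

    def test_termini_flagged_undefined(self):
        geom = phi_psi(ideal_helix(8))
        assert np.isnan(geom.phi[0]) and np.isnan(geom.psi[-1])
        assert np.isfinite(geom.phi[1:]).all() and np.isfinite(geom.psi[:-1]).all()

    def test_tiny_chain_rejected(self):
        model = ideal_helix(5)
        one_res = type(model)([a for a in model.atoms if a.res_index == 1])
        with pytest.raises(ValueError):
            phi_psi(one_res)


class TestAmideHydrogen:
    def test_placed_h_bond_length_is_one_angstrom(self):
        model = place_amide_hydrogen(ideal_helix(10))
        for r in group_residues(model)[1:]:
            assert "H" in r.atoms
            assert np.linalg.norm(r.coord("H") - r.coord("N")) == pytest.approx(1.0)

    def test_first_residue_gets_no_h(self):
        model = place_amide_hydrogen(ideal_helix(10))
        assert "H" not in group_residues(model)[0].atoms

    def test_proline_gets_no_h(self):
        spec = BackboneSpec(
            np.full(8, -57.0), np.full(8, -47.0),
            res_names=["ALA", "ALA", "PRO", "ALA", "ALA", "ALA", "ALA", "ALA"],
        )
        model = place_amide_hydrogen(build_backbone(spec))
        residues = group_residues(model)
        assert "H" not in residues[2].atoms
        assert "H" in residues[3].atoms

    def test_h_opposes_previous_carbonyl(self):
        model = place_amide_hydrogen(ideal_helix(6))
        residues = group_residues(model)
        prev, cur = residues[2], residues[3]
        co = prev.coord("O") - prev.coord("C")
        nh = cur.coord("H") - cur.coord("N")
        cos = np.dot(co, nh) / (np.linalg.norm(co) * np.linalg.norm(nh))
        assert cos == pytest.approx(-1.0, abs=1e-9)


def _four_residue_geometry(n_xyz, h_xyz, c_xyz, o_xyz):
    """Geometry scaffold with residue 0 the acceptor (C, O) and residue 3
    the donor (N, H)."""
    nan3 = np.full((4, 3), np.nan)
    n = nan3.copy(); n[3] = n_xyz
    h = nan3.copy(); h[3] = h_xyz
    c = nan3.copy(); c[0] = c_xyz
    o = nan3.copy(); o[0] = o_xyz
    return BackboneGeometry(
        res_indices=np.arange(1, 5), res_names=["ALA"] * 4,
        n=n, ca=nan3.copy(), c=c, o=o, h=h,
        phi=np.full(4, np.nan), psi=np.full(4, np.nan), omega=np.full(4, np.nan),
    )


class TestHbondEnergy:
    def test_ideal_linear_geometry_is_bonding(self):
        # O at origin, C=O pointing at the donor N 2.9 Å away, H in line
        geom = _four_residue_geometry(
            n_xyz=[2.9, 0, 0], h_xyz=[1.9, 0, 0], c_xyz=[-1.231, 0, 0],
            o_xyz=[0, 0, 0],
        )
        e = hbond_energy(3, 0, geom)
        hand = KS_COUPLING * (1 / 2.9 + 1 / (2.9 + 1.231 - 1.0) - 1 / 1.9 - 1 / (2.9 + 1.231))
        assert e == pytest.approx(hand, abs=1e-9)
        assert e < -0.5

    def test_distant_pair_is_negligible(self):
        geom = _four_residue_geometry(
            n_xyz=[15.0, 0, 0], h_xyz=[14.0, 0, 0], c_xyz=[-1.231, 0, 0],
            o_xyz=[0, 0, 0],
        )
        e = hbond_energy(3, 0, geom)
        assert abs(e) < 0.5

    def test_sequence_adjacent_pair_excluded(self):
        geom = _four_residue_geometry(
            n_xyz=[2.9, 0, 0], h_xyz=[1.9, 0, 0], c_xyz=[-1.231, 0, 0],
            o_xyz=[0, 0, 0],
        )
        assert hbond_energy(1, 0, geom) == np.inf

    def test_helix_bond_pattern_is_i_to_i_plus_4(self):
        geom = phi_psi(place_amide_hydrogen(ideal_helix(20)))
        bonds = compute_hbonds(geom)
        assert bonds, "ideal helix must form backbone H-bonds"
        seps = {b.donor_res - b.acceptor_res for b in bonds}
        assert seps == {4}
        assert all(b.energy < -0.5 for b in bonds)
        assert all(abs(b.donor_res - b.acceptor_res) >= 2 for b in bonds)


class TestSecondaryStructure:
    def test_ideal_helix_dominantly_h(self, helix20):
        ss = assign_secondary_structure(helix20)
        assert ss.classes.count("H") >= 16
        assert ss.classes.count("E") == 0

    def test_antiparallel_pair_central_strand(self, paired_strands):
        ss = assign_secondary_structure(paired_strands)
        n = len(ss.classes) // 2
        # central residues of both strands sit in the bridge ladder
        assert all(c == "E" for c in ss.classes[2 : n - 2])
        assert all(c == "E" for c in ss.classes[n + 2 : 2 * n - 2])

    def test_single_strand_has_no_helix(self, strand20):
        ss = assign_secondary_structure(strand20)
        assert ss.classes.count("H") == 0

    def test_random_coil_mostly_coil_or_turn(self, coil20):
        ss = assign_secondary_structure(coil20)
        frac = (ss.classes.count("C") + ss.classes.count("T")) / len(ss.classes)
        assert frac >= 0.8


class TestPercentages:
    def test_table_row_fractions(self):
        # 116 helix residues of 312 and 49 strand residues of 312
        classes = ["H"] * 116 + ["E"] * 49 + ["C"] * (312 - 165)
        ss = ss_percentages(classes)
        assert round(ss.pct_helix, 2) == 37.18
        assert round(ss.pct_strand, 2) == 15.71

    def test_all_coil_degenerate(self):
        ss = ss_percentages(["C"] * 10)
        assert ss.pct_coil == 100.0
        assert ss.pct_helix == ss.pct_310 == ss.pct_strand == ss.pct_turn == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_five_classes_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        classes = rng.choice(list("HGETC"), size=int(rng.integers(3, 400)))
        ss = ss_percentages(list(classes))
        assert sum(ss.percentages().values()) == pytest.approx(100.0, abs=0.01)

    def test_empty_assignment_rejected(self):
        with pytest.raises(ValueError):
            ss_percentages([], 0)


class TestRamachandranScore:
    @staticmethod
    def _geom_from_angles(phi, psi):
        n = len(phi)
        nan3 = np.full((n, 3), np.nan)
        return BackboneGeometry(
            res_indices=np.arange(1, n + 1), res_names=["ALA"] * n,
            n=nan3, ca=nan3, c=nan3, o=nan3, h=nan3,
            phi=np.asarray(phi, dtype=float), psi=np.asarray(psi, dtype=float),
            omega=np.full(n, 180.0),
        )

    def test_reference_sample_scores_near_zero(self):
        from foldkit.conformation_analysis import RAMA_BASINS, RAMA_SIGMA, RAMA_WEIGHTS

        rng = np.random.default_rng(77)
        comp = rng.choice(len(RAMA_BASINS), size=1000, p=RAMA_WEIGHTS)
        sample = RAMA_BASINS[comp] + rng.normal(0, RAMA_SIGMA, size=(1000, 2))
        wrapped = (sample + 180.0) % 360.0 - 180.0
        z = ramachandran_score(self._geom_from_angles(wrapped[:, 0], wrapped[:, 1]))
        assert -0.5 < z < 0.5

    def test_uniform_torsions_score_badly(self):
        rng = np.random.default_rng(78)
        z = ramachandran_score(
            self._geom_from_angles(
                rng.uniform(-180, 180, 200), rng.uniform(-180, 180, 200)
            )
        )
        assert z < -3

    def test_helix_scores_better_than_uniform(self, helix20):
        rng = np.random.default_rng(79)
        z_helix = ramachandran_score(phi_psi(helix20))
        z_unif = ramachandran_score(
            self._geom_from_angles(
                rng.uniform(-180, 180, 50), rng.uniform(-180, 180, 50)
            )
        )
        assert z_helix > z_unif

    def test_too_few_defined_angles_rejected(self):
        with pytest.raises(ValueError):
            ramachandran_score(self._geom_from_angles([-57.0] * 5, [-47.0] * 5))

    def test_log_density_is_periodic(self):
        assert rama_log_density(-179.0, 100.0) == pytest.approx(
            rama_log_density(181.0, 100.0), rel=1e-12
        )


class TestChirality:
    def test_l_fixture_has_no_violations(self, helix20):
        violations, z = chirality_check(helix20)
        assert violations == 0 and z == 0.0

    def test_mirror_flags_every_non_glycine(self, helix20):
        violations, z = chirality_check(mirror(helix20))
        n_non_gly = sum(1 for r in group_residues(helix20) if r.res_name != "GLY")
        assert violations == n_non_gly
        assert z == pytest.approx(100.0)

    def test_glycine_exempt(self):
        spec = BackboneSpec(
            np.full(8, -57.0), np.full(8, -47.0),
            res_names=["ALA", "GLY", "ALA", "GLY", "ALA", "ALA", "ALA", "ALA"],
        )
        violations, _ = chirality_check(mirror(build_backbone(spec)))
        assert violations == 6

    def test_selectively_mirrored_residues_counted(self):
        model = build_backbone(BackboneSpec(np.full(20, -57.0), np.full(20, -47.0)))
        flipped = {5, 10, 15}
        for r in group_residues(model):
            if r.res_index in flipped:
                # rebuild CB on the D side: negate the chirality torsion
                r.atoms["CB"].coord = _place(
                    r.coord("N"), r.coord("C"), r.coord("CA"), 1.521, 110.1, -34.0
                )
        violations, _ = chirality_check(model)
        assert violations == 3
        # oracle: per-residue sign of the N,C,CA,CB torsion
        signs = [
            dihedral(r.coord("N"), r.coord("C"), r.coord("CA"), r.coord("CB")) < 0
            for r in group_residues(model)
        ]
        assert sum(signs) == 3


class TestBackboneNormality:
    def test_reference_geometry_scores_zero(self, helix20):
        assert abs(backbone_normality(helix20)) < 0.1

    @staticmethod
    def _noisy(model, sigma, seed):
        noisy = model.copy()
        rng = np.random.default_rng(seed)
        for a in noisy.atoms:
            a.coord = a.coord + rng.normal(0, sigma, 3)
        return noisy

    def test_noise_drives_score_negative(self, helix20):
        assert backbone_normality(self._noisy(helix20, 0.05, seed=5)) < -1

    def test_score_decreases_monotonically_with_noise(self, helix20):
        zs = [
            backbone_normality(self._noisy(helix20, s, seed=6))
            for s in (0.01, 0.05, 0.1)
        ]
        assert zs[0] > zs[1] > zs[2]


class TestPackingScore:
    def test_compact_bundle_beats_extended_chain(self, bundle):
        assert packing_score(bundle) > packing_score(ideal_strand(30))

    def test_extended_chain_scores_far_negative(self):
        assert packing_score(ideal_strand(30)) < -2

    def test_deterministic_on_copies(self, bundle):
        assert packing_score(bundle) == packing_score(bundle.copy())

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            packing_score(ideal_helix(10))


class TestCavityVolumes:
    def test_hollow_shell_matches_sphere_volume(self):
        rep = cavity_volumes(hollow_shell(12.0, 5.0))
        expected = 4.0 / 3.0 * math.pi * 5.0**3
        assert rep.total_cavity == pytest.approx(expected, rel=0.15)
        assert rep.largest_cavity <= rep.total_cavity
        assert rep.cavity_count == 1

    def test_solid_ball_has_no_cavity(self):
        rep = cavity_volumes(hollow_shell(8.0, 0.0))
        assert rep.total_cavity == 0.0
        assert rep.cavity_count == 0

    def test_open_channel_drains_cavity(self):
        rep = cavity_volumes(hollow_shell(12.0, 5.0, channel_width=4.0))
        assert rep.total_cavity == 0.0

    def test_grid_halving_converges(self):
        shell = hollow_shell(12.0, 5.0)
        coarse = cavity_volumes(shell, grid=0.7).total_cavity
        fine = cavity_volumes(shell, grid=0.35).total_cavity
        assert abs(fine - coarse) / coarse < 0.10

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            cavity_volumes(hollow_shell(8.0, 0.0), grid=0.0)


class TestScoreInvariances:
    def test_quality_scores_rigid_motion_invariant(self, helix20):
        from scipy.spatial.transform import Rotation

        moved = helix20.copy()
        R = Rotation.from_rotvec([0.7, -0.2, 1.5]).as_matrix()
        t = np.array([11.0, -4.0, 8.0])
        for a in moved.atoms:
            a.coord = R @ a.coord + t
        base = quality_report(helix20)
        rot = quality_report(moved)
        assert rot.bbc_z == pytest.approx(base.bbc_z, rel=1e-9, abs=1e-9)
        assert rot.pack_z == pytest.approx(base.pack_z, rel=1e-9)
        assert rot.rama_z == pytest.approx(base.rama_z, rel=1e-9)
        assert rot.chirality_violations == base.chirality_violations

    def test_mirroring_degrades_rama_and_chirality(self, helix20):
        base = quality_report(helix20)
        mirrored = quality_report(mirror(helix20))
        assert mirrored.chirality_violations == 20
        assert mirrored.rama_z < base.rama_z  # helical basin empties
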