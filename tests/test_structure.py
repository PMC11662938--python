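"""Solenoid geometry, screw decomposition, distances, FRET-pair screening."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pprfret import (
    CoordinateSet,
    RepeatSpec,
    SolenoidSpec,
    fit_superhelix,
    generate_ideal_solenoid,
    inter_repeat_transforms,
    pair_distances,
    predict_fret_from_distance,
    read_structure,
    screen_fret_pairs,
)
from pprfret.structure import DegenerateGeometryError, kabsch

BOUND = SolenoidSpec(rise=4.8, twist=40.0, radius=25.0, n_repeats=18)
APO = SolenoidSpec(rise=8.5, twist=36.0, radius=25.0, n_repeats=18)


class TestReadWrite:
    def test_pdb_round_trip(self, tmp_path):
        cs = generate_ideal_solenoid(BOUND)
        path = tmp_path / "ideal.pdb"
        cs.write_pdb(path)
        spec = RepeatSpec(chain="A", ranges=list(cs.repeat_annotation))
        back = read_structure(path, spec)
        assert back.n_repeats == 18
        # PDB format stores 3 decimals
        np.testing.assert_allclose(np.sort(back.xyz, axis=0), np.sort(cs.xyz, axis=0), atol=1e-3)

    def test_overlapping_annotation_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            CoordinateSet(
                chain=np.array(["A"]),
                resnum=np.array([1]),
                atom_name=np.array(["CA"]),
                xyz=np.zeros((1, 3)),
                repeat_annotation=[(1, 35), (30, 64), (65, 99)],
            )

    def test_missing_range_named_in_error(self, tmp_path):
        cs = generate_ideal_solenoid(BOUND)
        path = tmp_path / "ideal.pdb"
        cs.write_pdb(path)
        spec = RepeatSpec(chain="A", ranges=[(1, 35), (36, 70), (5000, 5035)])
        with pytest.raises(ValueError, match="5000"):
            read_structure(path, spec)


class TestFitSuperhelix:
    def test_recovers_generation_parameters(self):
        par = fit_superhelix(generate_ideal_solenoid(BOUND))
        assert par.rise == pytest.approx(4.8, abs=1e-6)
        assert par.twist == pytest.approx(40.0, abs=1e-6)
        assert par.radius == pytest.approx(25.0, abs=1e-6)
        assert par.pitch == pytest.approx(43.2, abs=1e-6)

    def test_apo_parameters_and_derived_quantities(self):
        par = fit_superhelix(generate_ideal_solenoid(APO))
        assert par.pitch == pytest.approx(85.0, abs=1e-6)
        assert par.repeats_per_turn == pytest.approx(10.0, abs=1e-6)
        # type invariant: pitch = rise * 360 / twist
        assert par.pitch == pytest.approx(par.rise * 360.0 / par.twist, rel=1e-9)

    def test_invariant_under_rigid_motion(self):
        cs = generate_ideal_solenoid(BOUND)
        R = Rotation.from_euler("zyx", [31, -54, 12], degrees=True).as_matrix()
        t = np.array([104.0, -77.0, 13.0])
        par0 = fit_superhelix(cs)
        par1 = fit_superhelix(cs.transformed(R, t))
        assert par1.rise == pytest.approx(par0.rise, abs=1e-9)
        assert par1.twist == pytest.approx(par0.twist, abs=1e-9)
        assert par1.radius == pytest.approx(par0.radius, abs=1e-9)

    def test_collinear_centroids_rejected(self):
        n = 8
        cs = CoordinateSet(
            chain=np.array(["A"] * n),
            resnum=np.arange(1, n * 35, 35),
            atom_name=np.array(["CA"] * n),
            xyz=np.column_stack([np.zeros(n), np.zeros(n), np.arange(n) * 4.8]),
            repeat_annotation=[(1 + 35 * k, 35 + 35 * k) for k in range(n)],
        )
        with pytest.raises(DegenerateGeometryError):
            fit_superhelix(cs)


class TestInterRepeatTransforms:
    def test_identity_conformations(self):
        cs = generate_ideal_solenoid(APO)
        tfs = inter_repeat_transforms(cs, cs)
        assert max(t.rotation_angle for t in tfs) < 1e-5
        assert max(t.rmsd for t in tfs) < 1e-9

    def test_constructed_hinge_rotation_recovered(self):
        A = generate_ideal_solenoid(APO)
        xyz = A.xyz.copy()
        axis = np.array([0.3, -0.5, 0.81])
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.radians(12.0) * axis).as_matrix()
        pivot = xyz[A.repeat_mask(5)].mean(axis=0)
        sel = A.resnum > A.repeat_annotation[5][1]
        xyz[sel] = (xyz[sel] - pivot) @ R.T + pivot
        B = CoordinateSet(A.chain.copy(), A.resnum.copy(), A.atom_name.copy(), xyz,
                          list(A.repeat_annotation))
        tfs = inter_repeat_transforms(A, B)
        assert tfs[5].rotation_angle == pytest.approx(12.0, abs=1e-6)
        assert np.abs(np.abs(tfs[5].screw_axis @ axis) - 1.0) < 1e-9

    def test_screw_recomposition(self):
        A = generate_ideal_solenoid(APO)
        B = generate_ideal_solenoid(BOUND)
        tfs = inter_repeat_transforms(A, B)
        rng = np.random.default_rng(0)
        pts = rng.normal(scale=20.0, size=(6, 3))
        for t in tfs:
            assert np.abs(t.apply(pts) - t.apply_screw(pts)).max() < 1e-9
            assert abs(np.linalg.norm(t.screw_axis) - 1.0) < 1e-9
            assert 0 <= t.rotation_angle <= 180

    def test_mismatched_atoms_reported(self):
        A = generate_ideal_solenoid(APO)
        B = generate_ideal_solenoid(BOUND)
        B2 = CoordinateSet(B.chain.copy(), B.resnum + 1, B.atom_name.copy(), B.xyz,
                           list(B.repeat_annotation))
        with pytest.raises(ValueError, match="match"):
            inter_repeat_transforms(A, B2)


class TestDistancesAndFret:
    def test_elementary_distances(self):
        cs = CoordinateSet(
            chain=np.array(["A", "A"]),
            resnum=np.array([1, 2]),
            atom_name=np.array(["CA", "CA"]),
            xyz=np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]),
        )
        out = pair_distances(cs, cs, [(1, 2)])
        assert out[0]["r_A"] == pytest.approx(5.0)

    def test_missing_atom_flagged_others_computed(self):
        cs = CoordinateSet(
            chain=np.array(["A", "A"]),
            resnum=np.array([1, 2]),
            atom_name=np.array(["CA", "CA"]),
            xyz=np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]),
        )
        out = pair_distances(cs, cs, [(1, 99), (1, 2)])
        assert "error" in out[0] and out[1]["r_A"] == pytest.approx(5.0)

    def test_forster_curve(self):
        assert predict_fret_from_distance(54.0, 54.0) == pytest.approx(0.5)
        assert predict_fret_from_distance(40.0, 54.0) == pytest.approx(0.8582, abs=1e-4)
        rs = np.linspace(10, 150, 50)
        es = predict_fret_from_distance(rs, 54.0)
        assert np.all(np.diff(es) < 0) and es[-1] < 0.01
        with pytest.raises(ValueError):
            predict_fret_from_distance(10.0, 0.0)


class TestScreening:
    def test_ideal_conformations_retain_contrast_pair(self):
        apo = generate_ideal_solenoid(APO)
        bound = generate_ideal_solenoid(BOUND)
        hits = screen_fret_pairs(apo, bound, r0=54.0, separation=8)
        assert len(hits) > 0
        # chord-formula geometry: separations near 74 A (apo) vs 42 A (bound)
        c_apo = apo.repeat_centroids()
        c_bound = bound.repeat_centroids()
        assert np.linalg.norm(c_apo[0] - c_apo[8]) == pytest.approx(74.0, abs=1.0)
        assert np.linalg.norm(c_bound[0] - c_bound[8]) == pytest.approx(42.0, abs=1.0)
        top = hits[0]
        assert top.r_apo > 54.0 > top.r_bound
        assert np.all(np.diff([h.contrast for h in hits]) <= 1e-12)

    def test_identical_conformations_empty(self):
        apo = generate_ideal_solenoid(APO)
        assert screen_fret_pairs(apo, apo, r0=54.0, separation=8) == []


class TestKabsch:
    def test_exact_recovery_of_random_rigid_motion(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(12, 3))
        R = Rotation.random(random_state=2).as_matrix()
        t = np.array([1.0, -2.0, 3.0])
        Q = P @ R.T + t
        R2, t2, rmsd = kabsch(P, Q)
        assert np.allclose(R2, R, atol=1e-10) and np.allclose(t2, t, atol=1e-10)
        assert rmsd < 1e-10
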