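"""Kabsch superposition and domain displacement matrices."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from c5conform.displacement import (com, displacement_matrix, kabsch, match_ca)
from c5conform import synthetic_data as sd


def random_rigid(rng):
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.normal(0, 5, 3)
    return R, t


class TestKabsch:
    def test_identity(self):
        X = np.random.default_rng(0).normal(0, 3, (10, 3))
        tr = kabsch(X, X)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tr.translation, 0, atol=1e-12)
        assert tr.rmsd == pytest.approx(0, abs=1e-12)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 3, (12, 3))
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        mobile = X @ R.T + t  # reference rotated and shifted
        tr = kabsch(mobile, X)
        assert tr.rmsd < 1e-10
        assert np.allclose(tr.apply(mobile), X, atol=1e-9)
        assert np.allclose(tr.rotation, R.T, atol=1e-9)

    def test_optimal_among_random_alternatives(self):
        """Brute force: no random rigid transform beats the fitted one."""
        rng = np.random.default_rng(2)
        ref = rng.normal(0, 3, (10, 3))
        mobile = ref + rng.normal(0, 0.1, (10, 3))
        tr = kabsch(mobile, ref)
        best = tr.rmsd
        for _ in range(1000):
            R, t = random_rigid(rng)
            rmsd = np.sqrt(np.mean(np.sum((mobile @ R.T + t - ref) ** 2, axis=1)))
            assert rmsd >= best - 1e-12

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 3, (25, 3))
        mobile = ref + rng.normal(0, 0.3, (25, 3))
        tr = kabsch(mobile, ref)
        rot, _ = Rotation.align_vectors(ref - ref.mean(0), mobile - mobile.mean(0))
        assert np.allclose(tr.rotation, rot.as_matrix(), atol=1e-8)

    def test_reflection_excluded(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(0, 3, (10, 3))
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        tr = kabsch(mirrored, ref)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_raises(self):
        X = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch(X, X)


class TestCom:
    def test_mean_and_single_point(self):
        assert np.allclose(com([[0, 0, 0], [2, 0, 0]]), [1, 0, 0])
        assert np.allclose(com([[4.0, 5.0, 6.0]]), [4, 5, 6])

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 2, (30, 3))
        t = rng.normal(0, 10, 3)
        assert np.allclose(com(X + t), com(X) + t, atol=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            com(np.zeros((0, 3)))


class TestMatchCa:
    def test_full_pairing(self, toy_pair):
        apo, pert, _, dmap = toy_pair
        Xc, Xa = match_ca(pert, apo, "D1", dmap)
        assert Xc.shape == Xa.shape == (15, 3)

    def test_intersection_excludes_missing(self, toy_pair):
        apo, pert, _, dmap = toy_pair
        pruned = apo.select(lambda a: not (a.name == "CA" and
                                           1 <= a.residue_number <= 3))
        Xc, Xa = match_ca(pert, pruned, "D1", dmap)
        assert Xc.shape == (12, 3)

    def test_disjoint_sets_raise(self, toy_pair):
        apo, pert, _, dmap = toy_pair
        odd = apo.select(lambda a: a.residue_number % 2 == 1)
        even = pert.select(lambda a: a.residue_number % 2 == 0)
        with pytest.raises(ValueError, match="D1"):
            match_ca(even, odd, "D1", dmap)


class TestDisplacementMatrix:
    def test_self_comparison_is_zero(self, toy_pair):
        apo, _, _, dmap = toy_pair
        dm = displacement_matrix(apo, apo, dmap)
        for rec in dm.records.values():
            assert rec.translation == pytest.approx(0.0, abs=1e-9)
            assert rec.rotation == pytest.approx(0.0, abs=1e-5)

    def test_recovers_ground_truth_noise_free(self, toy_pair):
        apo, pert, truth, dmap = toy_pair
        dm = displacement_matrix(pert, apo, dmap)
        for rec in truth:
            r = dm.get(rec["reference_domain"], rec["target_domain"])
            assert r.translation == pytest.approx(rec["translation"], abs=1e-6)
            assert r.rotation == pytest.approx(rec["rotation"], abs=1e-6)

    def test_invariant_under_global_rigid_motion(self, toy_pair):
        apo, pert, _, dmap = toy_pair
        rng = np.random.default_rng(7)
        R, t = random_rigid(rng)
        moved = pert.copy()
        moved.set_coords(moved.coords() @ R.T + t)
        dm1 = displacement_matrix(pert, apo, dmap)
        dm2 = displacement_matrix(moved, apo, dmap)
        for key, rec in dm1.records.items():
            assert dm2.records[key].translation == pytest.approx(
                rec.translation, abs=1e-8)
            assert dm2.records[key].rotation == pytest.approx(
                rec.rotation, abs=1e-6)

    def test_pure_rotation_about_reference_com_reads_as_angle(self):
        """Rotating a target domain about an axis through the reference COM
        (axis perpendicular to the COM-COM vector) reports that exact angle
        and the induced COM shift."""
        base = sd.make_multidomain_toy(sd.ToySpec(n_domains=3,
                                                  residues_per_domain=15,
                                                  seed=9))
        apo, _, _, dmap = base
        from c5conform.structure_io import extract_ca
        com1 = np.mean([p for _, p in extract_ca(apo, "D1", dmap)], axis=0)
        com3 = np.mean([p for _, p in extract_ca(apo, "D3", dmap)], axis=0)
        v = com3 - com1
        axis = np.cross(v, [0.0, 0.0, 1.0])
        axis /= np.linalg.norm(axis)
        assert abs(np.dot(axis, v)) < 1e-9
        spec = sd.ToySpec(n_domains=3, residues_per_domain=15, seed=9,
                          applied_transforms=[
                              sd.DomainTransform(),
                              sd.DomainTransform(),
                              sd.DomainTransform(axis=tuple(axis), angle_deg=15.0,
                                                 pivot=tuple(com1))])
        apo2, pert, truth, dmap2 = sd.make_multidomain_toy(spec)
        rec = next(r for r in truth if r["reference_domain"] == "D1"
                   and r["target_domain"] == "D3")
        assert rec["rotation"] == pytest.approx(15.0, abs=1e-9)
        dm = displacement_matrix(pert, apo2, dmap2)
        got = dm.get("D1", "D3")
        assert got.rotation == pytest.approx(15.0, abs=1e-6)
        # chord length of the rotated COM
        expected_shift = 2.0 * np.linalg.norm(v) * np.sin(np.radians(7.5))
        assert got.translation == pytest.approx(expected_shift, abs=1e-6)

    def test_angles_within_range_and_frames_consistent(self, toy_pair):
        apo, pert, _, dmap = toy_pair
        dm = displacement_matrix(pert, apo, dmap)
        df_t, df_r = dm.translation_frame(), dm.rotation_frame()
        assert np.isnan(np.diag(df_t.to_numpy(float))).all()
        vals = df_r.to_numpy(float)
        vals = vals[~np.isnan(vals)]
        assert ((vals >= 0) & (vals <= 180)).all()

    def test_vertex_convention_switch_changes_little_when_fit_is_exact(self, toy_pair):
        apo, pert, _, dmap = toy_pair
        a = displacement_matrix(pert, apo, dmap, vertex="apo")
        b = displacement_matrix(pert, apo, dmap, vertex="complex")
        for key in a.records:
            assert a.records[key].rotation == pytest.approx(
                b.records[key].rotation, abs=1e-6)
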