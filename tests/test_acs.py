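"""Geometric-primitive fits and anatomical coordinate system construction."""

import math

import numpy as np
import pytest

from jointrom import (
    DegenerateGeometryError,
    build_long_bone_acs,
    build_pelvis_and_acetabular_acs,
    fit_cylinder,
    fit_line,
    fit_sphere,
    gram_schmidt_repair,
    validate_acs,
)
from jointrom.acs import ACS
from jointrom.synth import synth_landmarks

RNG = np.random.default_rng(13)


def sphere_points(center, radius, n=200, rng=None, noise=0.0):
    rng = rng or np.random.default_rng(0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = np.asarray(center) + radius * v
    if noise:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts


def cylinder_points(point, direction, radius, n=300, rng=None, noise=0.0,
                    half_shell=False):
    rng = rng or np.random.default_rng(1)
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    helper = np.array([1.0, 0, 0]) if abs(d[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    h = rng.uniform(-5, 5, n)
    phi = rng.uniform(0, math.pi if half_shell else 2 * math.pi, n)
    pts = (np.asarray(point) + np.outer(h, d)
           + radius * (np.outer(np.cos(phi), u) + np.outer(np.sin(phi), v)))
    if noise:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts


class TestFitSphere:
    def test_exact_recovery(self):
        s = fit_sphere(sphere_points((1, 2, 3), 5.0))
        assert np.allclose(s.center, [1, 2, 3], atol=1e-9)
        assert s.radius == pytest.approx(5.0, abs=1e-9)
        assert s.rms_residual < 1e-9

    def test_noisy_recovery_seeded(self):
        rng = np.random.default_rng(42)
        s = fit_sphere(sphere_points((1, 2, 3), 5.0, n=200, rng=rng, noise=0.05))
        assert np.linalg.norm(s.center - [1, 2, 3]) < 0.05

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(pts)

    def test_error_shrinks_with_n(self):
        # center error ~ 1/sqrt(n) at fixed noise, seeded
        errs = []
        for n in (100, 1600):
            runs = [np.linalg.norm(
                fit_sphere(sphere_points((0, 0, 0), 5.0, n=n,
                                         rng=np.random.default_rng(s),
                                         noise=0.1)).center)
                for s in range(8)]
            errs.append(np.mean(runs))
        assert errs[1] < errs[0] / 2.0  # sqrt(16) = 4x expected, allow 2x


class TestFitCylinder:
    def test_exact_recovery(self):
        c = fit_cylinder(cylinder_points((0, 0, 0), (0, 0, 1), 2.0))
        assert abs(abs(c.axis_direction[2]) - 1) < 1e-6
        assert c.radius == pytest.approx(2.0, abs=1e-6)

    def test_half_shell_noisy(self):
        rng = np.random.default_rng(7)
        c = fit_cylinder(cylinder_points((0, 0, 0), (0, 0, 1), 2.0, rng=rng,
                                         noise=0.02, half_shell=True))
        angle = math.degrees(math.acos(min(1.0, abs(c.axis_direction[2]))))
        assert angle < 1.0

    def test_reference_orients_axis(self):
        c = fit_cylinder(cylinder_points((0, 0, 0), (0, 0, 1), 2.0),
                         caudal_reference=(0, 0, -100))
        assert c.axis_direction[2] < 0

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_cylinder(np.tile([1.0, 2.0, 3.0], (10, 1)))


class TestFitLine:
    def test_collinear_exact(self):
        d = np.array([1.0, 1.0, 0]) / math.sqrt(2)
        pts = np.outer(np.linspace(-3, 3, 7), d)
        _, direction = fit_line(pts)
        assert np.allclose(np.abs(direction), np.abs(d), atol=1e-12)

    def test_ellipse_major_axis(self):
        th = np.linspace(0, 2 * math.pi, 50, endpoint=False)
        pts = np.column_stack([np.cos(th), 3 * np.sin(th), np.zeros_like(th)])
        _, direction = fit_line(pts)
        assert np.allclose(np.abs(direction), [0, 1, 0], atol=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_line(np.array([[1.0, 2.0, 3.0]]))


class TestLongBoneACS:
    @pytest.mark.parametrize("mode,end", [("keep_long_axis", "proximal"),
                                          ("keep_fe_axis", "distal")])
    def test_noiseless_recovery(self, mode, end):
        lm, truth = synth_landmarks("long_bone")
        acs = build_long_bone_acs(lm, mode=mode, end=end)
        t = truth[end]
        assert np.allclose(acs.origin, t["origin"], atol=1e-6)
        assert np.allclose(acs.x_axis, t["x_axis"], atol=1e-6)
        assert abs(abs(np.dot(acs.z_axis, t["z_axis"])) - 1) < 1e-6

    def test_invariants_on_random_fixtures(self):
        for seed in range(5):
            rot = _random_rotation(seed)
            lm, _ = synth_landmarks("long_bone", rotation=rot,
                                    translation=RNG.normal(size=3), seed=seed)
            acs = build_long_bone_acs(lm, mode="keep_long_axis", end="proximal")
            rep = validate_acs(acs)
            assert rep["passed"], rep

    def test_retained_axis_rule(self):
        lm, _ = synth_landmarks("long_bone", rotation=_random_rotation(3))
        acs = build_long_bone_acs(lm, mode="keep_long_axis", end="proximal")
        expected_x = lm.distal_perimeter.mean(0) - lm.proximal_perimeter.mean(0)
        expected_x /= np.linalg.norm(expected_x)
        assert np.allclose(acs.x_axis, expected_x, atol=1e-12)

        acs2 = build_long_bone_acs(lm, mode="keep_fe_axis", end="distal")
        _, line_dir = fit_line(lm.distal_perimeter)
        assert abs(abs(np.dot(acs2.z_axis, line_dir)) - 1) < 1e-12

    def test_rigid_motion_covariance(self):
        lm0, _ = synth_landmarks("long_bone")
        acs0 = build_long_bone_acs(lm0, mode="keep_long_axis", end="proximal")
        rot, t = _random_rotation(9), np.array([3.0, -2.0, 7.0])
        lm1, _ = synth_landmarks("long_bone", rotation=rot, translation=t)
        acs1 = build_long_bone_acs(lm1, mode="keep_long_axis", end="proximal")
        assert np.allclose(acs1.origin, rot @ acs0.origin + t, atol=1e-9)
        for ax in ("x_axis", "y_axis", "z_axis"):
            assert np.allclose(getattr(acs1, ax), rot @ getattr(acs0, ax),
                               atol=1e-9)

    def test_constructed_ellipse_fixture(self):
        # proximal ellipse in x=0 (major axis z), distal ellipse at (10,0,0)
        th = np.linspace(0, 2 * math.pi, 16, endpoint=False)
        prox = np.column_stack([np.zeros(16), np.cos(th), 2 * np.sin(th)])
        dist = prox * 0.8 + np.array([10.0, 0, 0])
        from jointrom import LandmarkSet
        lm = LandmarkSet(proximal_perimeter=prox, distal_perimeter=dist,
                         reference_points={"ventral": np.array([5.0, -3.0, 0])})
        acs = build_long_bone_acs(lm, mode="keep_long_axis", end="proximal")
        assert np.allclose(acs.x_axis, [1, 0, 0], atol=1e-9)
        assert abs(abs(acs.z_axis[2]) - 1) < 1e-9
        assert validate_acs(acs)["passed"]


class TestPelvisACS:
    def test_symmetric_fixture(self):
        sets, truth = synth_landmarks("pelvis")
        pelvis, left, right = build_pelvis_and_acetabular_acs(
            sets["left_acet"], sets["right_acet"], sets["sacral_body"],
            sets["caudal_ref"])
        assert np.allclose(pelvis.y_axis, [0, 1, 0], atol=1e-5)
        assert np.allclose(pelvis.origin, truth["origin"], atol=1e-5)
        assert np.allclose(left.origin, truth["left_center"], atol=1e-5)
        assert np.allclose(right.origin, truth["right_center"], atol=1e-5)
        for a in (pelvis, left, right):
            assert validate_acs(a)["passed"]
        # hip LAR points out of each socket
        assert np.dot(right.x_axis, pelvis.y_axis) > 0.99
        assert np.dot(left.x_axis, -pelvis.y_axis) > 0.99

    def test_yaw_removed_pitch_kept(self):
        # cylinder axis with yaw 20 and pitch 10: X keeps the pitch only
        yaw, pitch = math.radians(20), math.radians(10)
        axis = np.array([math.cos(pitch) * math.cos(yaw),
                         math.cos(pitch) * math.sin(yaw),
                         -math.sin(pitch)])
        projected = axis - axis[1] * np.array([0.0, 1.0, 0])
        projected /= np.linalg.norm(projected)
        sets, _ = synth_landmarks("pelvis")
        sac = cylinder_points((8, 0, 2), axis, 1.2,
                              rng=np.random.default_rng(5))
        pelvis, _, _ = build_pelvis_and_acetabular_acs(
            sets["left_acet"], sets["right_acet"], sac, (-100, 0, 20))
        assert abs(np.dot(pelvis.x_axis, pelvis.y_axis)) < 1e-9
        assert abs(abs(np.dot(pelvis.x_axis, projected)) - 1) < 1e-5

    def test_coincident_centroids_rejected(self):
        sets, _ = synth_landmarks("pelvis")
        with pytest.raises(DegenerateGeometryError):
            build_pelvis_and_acetabular_acs(
                sets["left_acet"], sets["left_acet"], sets["sacral_body"],
                sets["caudal_ref"])


class TestValidateACS:
    def test_exact_triad_passes(self):
        a = ACS(origin=np.zeros(3), x_axis=np.array([1.0, 0, 0]),
                y_axis=np.array([0, 1.0, 0]), z_axis=np.array([0, 0, 1.0]))
        rep = validate_acs(a)
        assert rep["passed"]
        assert all(v == 0 for v in rep["residuals"].values())

    def test_perturbed_triad_fails_then_repairs(self):
        y = np.array([math.sin(1e-3), math.cos(1e-3), 0.0])
        a = ACS(origin=np.zeros(3), x_axis=np.array([1.0, 0, 0]),
                y_axis=y, z_axis=np.array([0, 0, 1.0]))
        assert not validate_acs(a)["passed"]
        assert validate_acs(gram_schmidt_repair(a))["passed"]


def _random_rotation(seed):
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q
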