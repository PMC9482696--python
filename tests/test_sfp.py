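"""Spherical frame projections, regions, RoM summaries, comparisons."""

import numpy as np
import pytest

from jointrom import (
    DegenerateGeometryError,
    IncompatibleDataError,
    PoseSequence,
    RegionTooLargeError,
    build_region,
    build_regions,
    compare_invivo_exvivo,
    euler_to_matrix,
    geodesic_angle,
    point_in_region,
    pool_specimens,
    project_sfp,
    rom_summary,
)
from jointrom.reference import (
    HIP_ROM,
    KNEE_ROM,
    published_range,
    range_is_exact,
    reference_summary,
)
from jointrom.sfp import AXES, round_half_away
from util import spherical_winding_inside

RNG = np.random.default_rng(4)


def cap_points(center, radius_deg, n, rng):
    """Random unit vectors within an angular cap."""
    c = np.asarray(center, dtype=float)
    c = c / np.linalg.norm(c)
    helper = np.array([1.0, 0, 0]) if abs(c[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(c, helper)
    u /= np.linalg.norm(u)
    v = np.cross(c, u)
    ang = np.radians(radius_deg) * np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * np.pi, n)
    return (np.outer(np.cos(ang), c)
            + np.outer(np.sin(ang) * np.cos(phi), u)
            + np.outer(np.sin(ang) * np.sin(phi), v))


class TestProjectSFP:
    def test_identity_pose_tips(self):
        trace = project_sfp(PoseSequence.from_euler([(0, 0, 0)]))
        assert np.allclose(trace.x_tips[0], [1, 0, 0])
        assert np.allclose(trace.y_tips[0], [0, 1, 0])
        assert np.allclose(trace.z_tips[0], [0, 0, 1])

    def test_pure_fe_sweep_geometry(self):
        fe = np.linspace(-60, 60, 41)
        seq = PoseSequence.from_euler(
            np.column_stack([fe, np.zeros_like(fe), np.zeros_like(fe)]))
        trace = project_sfp(seq)
        assert np.allclose(trace.z_tips, [0, 0, 1], atol=1e-12)
        assert np.allclose(trace.x_tips[:, 2], 0, atol=1e-12)
        assert np.allclose(trace.y_tips[:, 2], 0, atol=1e-12)

    def test_tip_equals_matrix_column(self):
        r = euler_to_matrix((64, 22, -73))
        trace = project_sfp(PoseSequence.from_euler([(64, 22, -73)]))
        assert np.allclose(trace.z_tips[0], r[:, 2], atol=1e-12)
        assert np.allclose(trace.x_tips[0], r[:, 0], atol=1e-12)

    def test_tips_unit_norm_and_displacement_bound(self):
        seq = PoseSequence.from_euler(RNG.uniform(-70, 70, size=(50, 3)))
        trace = project_sfp(seq)
        for tips in (trace.x_tips, trace.y_tips, trace.z_tips):
            assert np.allclose(np.linalg.norm(tips, axis=1), 1, atol=1e-9)
        for i in range(0, 48, 7):
            rot_angle = geodesic_angle(seq.frames[i], seq.frames[i + 1])
            for tips in (trace.x_tips, trace.y_tips, trace.z_tips):
                assert geodesic_angle(tips[i], tips[i + 1]) <= rot_angle + 1e-9


class TestBuildRegion:
    def test_octant_corner_triangle(self):
        tips = np.eye(3)
        region = build_region(tips)
        assert len(region.boundary) == 3
        for corner in tips:
            assert any(np.allclose(corner, b, atol=1e-9)
                       for b in region.boundary)

    def test_cap_hull_contains_inputs(self):
        tips = cap_points([0, 0, 1], 20, 500, RNG)
        region = build_region(tips)
        assert all(point_in_region(p, region, tol=1e-7) for p in tips)

    def test_antipodal_tips_rejected(self):
        tips = np.array([[0, 0, 1.0], [0, 0, -1.0], [1.0, 0, 0]])
        with pytest.raises(RegionTooLargeError):
            build_region(tips)

    def test_too_few_distinct_tips(self):
        with pytest.raises(DegenerateGeometryError):
            build_region(np.array([[0, 0, 1.0], [0, 0, 1.0]]))

    def test_alpha_shape_hugs_nonconvex_cloud(self):
        rng = np.random.default_rng(11)
        a = cap_points(euler_to_matrix((0, 25, 0))[:, 2], 8, 300, rng)
        b = cap_points(euler_to_matrix((0, -25, 0))[:, 2], 8, 300, rng)
        bridge = cap_points([0, 0, 1], 3, 50, rng)
        tips = np.vstack([a, b, bridge])
        hull = build_region(tips, method="convex_hull")
        alpha = build_region(tips, method="alpha_shape", alpha_deg=15.0)
        assert alpha._poly.area <= hull._poly.area + 1e-12


class TestPointInRegion:
    def test_centroid_and_boundary_inside(self):
        region = build_region(cap_points([0, 0, 1], 15, 200, RNG))
        assert point_in_region(region.centroid, region)
        for b in region.boundary:
            assert point_in_region(b, region)

    def test_agrees_with_winding_oracle(self):
        region = build_region(cap_points([0.3, -0.2, 0.93], 25, 400, RNG))
        queries = cap_points(region.centroid, 40, 2000, RNG)
        for q in queries:
            assert point_in_region(q, region) == \
                spherical_winding_inside(q, region.boundary)

    def test_opposite_hemisphere_false(self):
        region = build_region(cap_points([0, 0, 1], 15, 100, RNG))
        assert not point_in_region(np.array([0, 0, -1.0]), region)


class TestRomSummary:
    def test_reference_hip_fe_range(self):
        # rebuilding the published Sal10 extrema reproduces range 114
        summary = reference_summary("hip", "Sal10 ex vivo")
        assert summary.rounded_table()["FE"]["range"] == 114
        assert summary.axes["FE"].max == 29 and summary.axes["FE"].min == -85

    @pytest.mark.parametrize("joint,table", [("hip", HIP_ROM), ("knee", KNEE_ROM)])
    def test_all_published_ranges_within_one_degree(self, joint, table):
        for specimen in table:
            summary = reference_summary(joint, specimen)
            rounded = summary.rounded_table()
            for axis in AXES:
                published = published_range(joint, specimen, axis)
                assert abs(rounded[axis]["range"] - published) <= 1
                if range_is_exact(joint, specimen, axis):
                    assert rounded[axis]["range"] == published

    def test_constant_sequence_zero_ranges(self):
        seq = PoseSequence.from_euler([(10, 5, -20)] * 4)
        s = rom_summary(seq)
        for axis in AXES:
            assert s.axes[axis].range == pytest.approx(0, abs=1e-9)
            assert s.axes[axis].max == pytest.approx(s.axes[axis].min)

    def test_sweep_with_known_limits(self):
        fe = np.arange(-40.0, 71.0, 1.0)
        seq = PoseSequence.from_euler(
            np.column_stack([fe, np.full_like(fe, 5.0), np.full_like(fe, -10.0)]))
        s = rom_summary(seq)
        assert s.axes["FE"].max == pytest.approx(70, abs=1)
        assert s.axes["FE"].min == pytest.approx(-40, abs=1)
        assert s.axes["FE"].at_max[1:] == pytest.approx((5.0, -10.0))

    def test_order_invariance_and_tie_break(self):
        angles = RNG.uniform(-50, 50, size=(30, 3))
        s1 = rom_summary(PoseSequence.from_euler(angles))
        s2 = rom_summary(PoseSequence.from_euler(angles[::-1]))
        for axis in AXES:
            assert s1.axes[axis].max == s2.axes[axis].max
            assert s1.axes[axis].min == s2.axes[axis].min
        tied = PoseSequence.from_euler([(10, 0, 0), (10, 0, 5)])
        assert rom_summary(tied).axes["FE"].max_frame == 0

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(-0.5) == -1
        assert round_half_away(2.4) == 2

    def test_mirror_commutes_with_summary(self):
        angles = RNG.uniform(-60, 60, size=(40, 3))
        seq = PoseSequence.from_euler(angles)
        sm = rom_summary(seq.mirrored())
        s = rom_summary(seq)
        assert sm.axes["FE"].max == pytest.approx(-s.axes["FE"].min, abs=1e-9)
        assert sm.axes["LAR"].min == pytest.approx(-s.axes["LAR"].max, abs=1e-9)
        assert sm.axes["ABAD"].max == pytest.approx(s.axes["ABAD"].max, abs=1e-9)


class TestPoolingAndComparison:
    @staticmethod
    def _trace(seed=0, n=300, spread=30, meta=None):
        rng = np.random.default_rng(seed)
        angles = rng.uniform(-spread, spread, size=(n, 3))
        seq = PoseSequence.from_euler(angles, meta=meta or {"joint": "hip",
                                                            "side": "right"})
        return project_sfp(seq), seq

    def test_pool_idempotent_up_to_duplicates(self):
        trace, _ = self._trace()
        pooled = pool_specimens([trace, trace])
        r1 = build_region(trace.z_tips)
        r2 = build_region(pooled.z_tips)
        assert np.allclose(sorted(map(tuple, r1.boundary)),
                           sorted(map(tuple, r2.boundary)), atol=1e-9)

    def test_pooled_region_contains_member_tips(self):
        t1, _ = self._trace(seed=1)
        t2, _ = self._trace(seed=2, spread=20)
        pooled = pool_specimens([t1, t2])
        regions = build_regions(pooled)
        for axis in AXES:
            for tip in t1.tips(axis)[::29]:
                assert point_in_region(tip, regions[axis], tol=1e-7)

    def test_left_side_guard(self):
        trace, _ = self._trace(meta={"joint": "hip", "side": "left"})
        with pytest.raises(IncompatibleDataError):
            pool_specimens([trace])

    def test_mixed_joint_guard(self):
        t1, _ = self._trace(meta={"joint": "hip", "side": "right"})
        t2, _ = self._trace(meta={"joint": "knee", "side": "right"})
        with pytest.raises(IncompatibleDataError):
            pool_specimens([t1, t2])

    def test_contained_trace_fully_inside(self):
        ex, _ = self._trace(seed=3, spread=40, meta={"joint": "hip",
                                                     "side": "right"})
        regions = build_regions(ex)
        inner, seq = self._trace(seed=4, spread=15)
        report = compare_invivo_exvivo(inner, regions,
                                       invivo_summary=rom_summary(seq),
                                       exvivo_summaries=[])
        assert all(v == 1.0 for v in report.inside_fraction.values())
        assert report.null_pose_reachable  # spread includes the identity pose

    def test_displaced_frames_listed(self):
        ex, _ = self._trace(seed=5, spread=30)
        regions = build_regions(ex)
        rng = np.random.default_rng(6)
        angles = rng.uniform(-10, 10, size=(100, 3))
        angles[::20, 0] = 170.0  # 5 of 100 frames far outside in FE
        inv = project_sfp(PoseSequence.from_euler(angles))
        report = compare_invivo_exvivo(inv, regions)
        assert report.inside_fraction["LAR"] == pytest.approx(0.95)
        assert report.outside_frames["LAR"] == [0, 20, 40, 60, 80]

    def test_region_excluding_identity(self):
        # ex vivo pose space far from the null pose: identity unreachable
        rng = np.random.default_rng(7)
        angles = np.column_stack([rng.uniform(60, 80, 100),
                                  rng.uniform(-5, 5, 100),
                                  rng.uniform(-5, 5, 100)])
        ex = project_sfp(PoseSequence.from_euler(angles))
        regions = build_regions(ex)
        report = compare_invivo_exvivo(ex, regions)
        assert not report.null_pose_reachable
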