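"""Spherical frame projections (SFPs), pose-space regions and RoM tables.

An SFP traces the unit axis tips of the distal ACS on a sphere fixed in
the proximal ACS, one point per axis per frame.  Unlike Euler-angle plots,
distances between points on the sphere faithfully represent distances
between poses and the picture has no gimbal-lock distortion.  The
conventional colouring is blue = FE (Z tip), green = ABAD (Y tip),
red = LAR (X tip).

Pose-space regions are built per axis by gnomonically projecting the tip
cloud about its spherical centroid (great circles map to straight lines,
so a planar convex hull corresponds to a spherical convex hull) and
taking either the planar convex hull (default) or an alpha shape for
non-convex clouds.  Membership tests use the same chart, with the
boundary counted as inside.

RoM tables report, per rotational axis, the extreme ZYX Euler angles with
the concomitant angles about the other two axes at the extremal pose —
the interaction of degrees of freedom.  Ranges are computed on unrounded
extrema and only then rounded to whole degrees, so a printed range can
differ from (rounded max - rounded min) by 1 degree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from .errors import (
    DegenerateGeometryError,
    EmptyInputError,
    IncompatibleDataError,
    RegionTooLargeError,
)
from .kinematics import (
    GIMBAL_LOCK_TOL,
    JointConvention,
    PoseSequence,
)

AXES = ("FE", "ABAD", "LAR")
#: SFP tip roles: which rotation-matrix column carries each axis tip.
AXIS_COLUMN = {"LAR": 0, "ABAD": 1, "FE": 2}  # X, Y, Z columns
AXIS_COLOR = {"FE": "blue", "ABAD": "green", "LAR": "red"}
#: Euler-array column per anatomical axis (FE, ABAD, LAR ordering).
EULER_COLUMN = {"FE": 0, "ABAD": 1, "LAR": 2}

_HEMISPHERE_MARGIN_DEG = 1e-6


def round_half_away(x) -> np.ndarray:
    """Round to nearest integer, ties away from zero (table convention)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


# ---------------------------------------------------------------------------
# SFP traces
# ---------------------------------------------------------------------------

@dataclass
class SFPTrace:
    """Axis-tip point clouds on the unit sphere, one tip per frame."""

    x_tips: np.ndarray
    y_tips: np.ndarray
    z_tips: np.ndarray
    meta: dict = field(default_factory=dict)

    def tips(self, axis: str) -> np.ndarray:
        return {"LAR": self.x_tips, "ABAD": self.y_tips, "FE": self.z_tips}[axis]

    def __len__(self) -> int:
        return len(self.z_tips)


def project_sfp(seq: PoseSequence) -> SFPTrace:
    """Trace the distal ACS axes on the proximal-frame unit sphere.

    The three tips per frame are the columns of the relative rotation
    matrix (the distal unit axes expressed in the proximal ACS).
    """
    seq.validate()
    f = seq.frames
    meta = dict(seq.meta)
    meta["colors"] = dict(AXIS_COLOR)
    return SFPTrace(x_tips=f[:, :, 0].copy(), y_tips=f[:, :, 1].copy(),
                    z_tips=f[:, :, 2].copy(), meta=meta)


# ---------------------------------------------------------------------------
# Spherical regions
# ---------------------------------------------------------------------------

@dataclass
class SphericalRegion:
    """Closed region on the unit sphere covered by one axis's tips.

    ``boundary`` is an ordered closed spherical polygon (unit vectors,
    counterclockwise seen from outside the sphere); membership is decided
    on the gnomonic chart about ``centroid`` stored in ``_chart``/``_poly``.
    """

    axis_role: str
    boundary: np.ndarray
    centroid: np.ndarray
    max_angular_radius: float
    method: str
    _chart: tuple = field(default=None, repr=False)
    _poly: Polygon = field(default=None, repr=False)


def _spherical_centroid(tips: np.ndarray) -> np.ndarray:
    m = tips.mean(axis=0)
    n = np.linalg.norm(m)
    if n < 1e-9:
        raise RegionTooLargeError("tips have no well-defined spherical centroid")
    return m / n


def _chart_basis(c: np.ndarray):
    helper = np.array([0.0, 0.0, 1.0]) if abs(c[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(c, helper)
    u /= np.linalg.norm(u)
    v = np.cross(c, u)
    return u, v


def _gnomonic(tips: np.ndarray, chart) -> np.ndarray:
    c, u, v = chart
    w = tips @ c
    if np.any(w <= math.cos(math.radians(90.0 - _HEMISPHERE_MARGIN_DEG))):
        raise RegionTooLargeError(
            "tips span more than a hemisphere about their centroid; "
            "split the data before building a region")
    return np.column_stack([tips @ u / w, tips @ v / w])


def _inverse_gnomonic(xy: np.ndarray, chart) -> np.ndarray:
    c, u, v = chart
    pts = c[None, :] + xy[:, 0:1] * u[None, :] + xy[:, 1:2] * v[None, :]
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def build_region(tips: np.ndarray, axis_role: str = "FE",
                 method: str = "convex_hull",
                 alpha_deg: float = 15.0) -> SphericalRegion:
    """Build the pose-space region covered by an axis-tip cloud.

    Tips are projected gnomonically about their spherical centroid (the
    cloud must fit in an open hemisphere); the planar convex hull
    (default) or an alpha shape at scale ``alpha_deg`` is taken and its
    boundary mapped back to the sphere.
    """
    tips = np.atleast_2d(np.asarray(tips, dtype=float))
    if len(np.unique(np.round(tips, 12), axis=0)) < 3:
        raise DegenerateGeometryError("need >= 3 distinct tips for a region")
    c = _spherical_centroid(tips)
    chart = (c, *_chart_basis(c))
    xy = _gnomonic(tips, chart)

    if method == "convex_hull":
        hull = ConvexHull(xy)
        ring = xy[hull.vertices]  # counterclockwise in the chart
        poly = Polygon(ring)
    elif method == "alpha_shape":
        poly = _alpha_shape(xy, math.tan(math.radians(alpha_deg)))
        ring = np.asarray(poly.exterior.coords[:-1])
    else:
        raise ValueError(f"unknown region method {method!r}")

    boundary = _inverse_gnomonic(ring, chart)
    radius = float(np.degrees(np.max(np.arccos(np.clip(tips @ c, -1.0, 1.0)))))
    return SphericalRegion(axis_role=axis_role, boundary=boundary, centroid=c,
                           max_angular_radius=radius, method=method,
                           _chart=chart, _poly=poly)


def _alpha_shape(xy: np.ndarray, alpha: float) -> Polygon:
    """Union of Delaunay triangles with circumradius below ``alpha``."""
    tri = Delaunay(xy)
    keep = []
    for simplex in tri.simplices:
        a, b, c = xy[simplex]
        la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c),
                      np.linalg.norm(a - b))
        s = 0.5 * (la + lb + lc)
        area2 = max(s * (s - la) * (s - lb) * (s - lc), 0.0)
        if area2 <= 0:
            continue
        circum_r = la * lb * lc / (4.0 * math.sqrt(area2))
        if circum_r < alpha:
            keep.append(Polygon(xy[simplex]))
    if not keep:
        raise DegenerateGeometryError(
            "alpha shape is empty; increase alpha_deg")
    merged = unary_union(keep)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    return Polygon(merged.exterior)


def point_in_region(p: np.ndarray, region: SphericalRegion,
                    tol: float = 1e-9) -> bool:
    """Closed membership test on the region's own gnomonic chart.

    Points outside the region's hemisphere return False; boundary points
    count as inside.
    """
    p = np.asarray(p, dtype=float)
    c, u, v = region._chart
    w = float(p @ c)
    if w <= 0:
        return False
    xy = Point(p @ u / w, p @ v / w)
    return region._poly.covers(xy) or region._poly.distance(xy) <= tol


# ---------------------------------------------------------------------------
# RoM summaries
# ---------------------------------------------------------------------------

@dataclass
class AxisRange:
    """Extremes about one axis with the concomitant angles at the extrema."""

    max: float
    min: float
    range: float
    at_max: tuple      # (fe, abad, lar) Euler triple at the maximal frame
    at_min: tuple
    max_frame: int
    min_frame: int


@dataclass
class RoMSummary:
    """Per-axis RoM with interaction of degrees of freedom.

    ``axes`` maps 'FE'/'ABAD'/'LAR' to :class:`AxisRange` on unrounded
    angles; :meth:`rounded_table` applies the whole-degree table view.
    """

    axes: dict
    meta: dict = field(default_factory=dict)
    gimbal_locked_frames: int = 0

    def rounded_table(self) -> dict:
        """Whole-degree view: every cell rounded half away from zero.

        The range is rounded from the unrounded range, so it may differ
        from rounded max - rounded min by one degree.
        """
        out = {}
        for axis, ar in self.axes.items():
            out[axis] = {
                "max": int(round_half_away(ar.max)),
                "min": int(round_half_away(ar.min)),
                "range": int(round_half_away(ar.range)),
                "at_max": tuple(int(x) for x in round_half_away(ar.at_max)),
                "at_min": tuple(int(x) for x in round_half_away(ar.at_min)),
            }
        return out


def rom_summary(seq: PoseSequence,
                convention: JointConvention | None = None) -> RoMSummary:
    """Per-axis max/min/range and concomitant angles from a pose sequence.

    Extremes are order statistics of the per-frame ZYX Euler angles; ties
    are broken by the earliest frame (numpy argmax/argmin).  Gimbal-locked
    frames participate under the lock convention (LAR = 0) and are counted
    in ``gimbal_locked_frames``.
    """
    euler = seq.to_euler()
    locked = int(np.sum(1.0 - np.abs(np.sin(np.radians(euler[:, 1])))
                        < GIMBAL_LOCK_TOL))
    axes = {}
    for axis in AXES:
        col = EULER_COLUMN[axis]
        imax = int(np.argmax(euler[:, col]))
        imin = int(np.argmin(euler[:, col]))
        vmax = float(euler[imax, col])
        vmin = float(euler[imin, col])
        axes[axis] = AxisRange(
            max=vmax, min=vmin, range=vmax - vmin,
            at_max=tuple(euler[imax]), at_min=tuple(euler[imin]),
            max_frame=imax, min_frame=imin,
        )
    meta = dict(seq.meta)
    if convention is not None:
        meta["convention"] = convention
    return RoMSummary(axes=axes, meta=meta, gimbal_locked_frames=locked)


def summary_from_extrema(extrema: dict, meta: dict | None = None) -> RoMSummary:
    """RoM summary from explicit per-axis extremal Euler triples.

    ``extrema`` maps each axis to ``(triple_at_max, triple_at_min)`` where
    each triple is (FE, ABAD, LAR) in degrees.  Used to re-analyse
    published extremal poses without the underlying frame data: ranges are
    recomputed from the extrema with the same arithmetic as
    :func:`rom_summary`.
    """
    axes = {}
    for axis, (at_max, at_min) in extrema.items():
        col = EULER_COLUMN[axis]
        vmax, vmin = float(at_max[col]), float(at_min[col])
        axes[axis] = AxisRange(max=vmax, min=vmin, range=vmax - vmin,
                               at_max=tuple(at_max), at_min=tuple(at_min),
                               max_frame=0, min_frame=0)
    return RoMSummary(axes=axes, meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# Pooling and in vivo vs ex vivo comparison
# ---------------------------------------------------------------------------

def pool_specimens(traces: list) -> SFPTrace:
    """Concatenate several specimens' SFP traces into one pooled trace.

    All traces must share joint and (right-side) convention; left-side
    traces must be mirrored before pooling (``PoseSequence.mirrored``),
    which flips their side metadata.
    """
    if not traces:
        raise EmptyInputError("nothing to pool")
    joints = {t.meta.get("joint") for t in traces}
    if len(joints) > 1:
        raise IncompatibleDataError(f"cannot pool mixed joints {joints}")
    for t in traces:
        if t.meta.get("side") == "left":
            raise IncompatibleDataError(
                "left-side trace must be mirrored to the right side before pooling")
    provenance = [t.meta.get("specimen", f"trace{i}") for i, t in enumerate(traces)]
    meta = dict(traces[0].meta)
    meta["specimens"] = provenance
    meta["pooled"] = True
    return SFPTrace(
        x_tips=np.concatenate([t.x_tips for t in traces]),
        y_tips=np.concatenate([t.y_tips for t in traces]),
        z_tips=np.concatenate([t.z_tips for t in traces]),
        meta=meta,
    )


def build_regions(trace: SFPTrace, method: str = "convex_hull",
                  alpha_deg: float = 15.0) -> dict:
    """Per-axis :class:`SphericalRegion` for a (pooled) trace."""
    return {axis: build_region(trace.tips(axis), axis_role=axis,
                               method=method, alpha_deg=alpha_deg)
            for axis in AXES}


@dataclass
class ComparisonReport:
    """In vivo pose space measured against pooled ex vivo regions."""

    inside_fraction: dict          # axis -> fraction of in vivo tips inside
    outside_frames: dict           # axis -> list of in vivo frame indices
    range_ratio: dict              # axis -> in vivo range / ex vivo range
    null_pose_reachable: bool      # identity tips inside all ex vivo regions


def compare_invivo_exvivo(
    invivo: SFPTrace,
    exvivo_regions: dict,
    invivo_summary: RoMSummary | None = None,
    exvivo_summaries: list | None = None,
) -> ComparisonReport:
    """Compare an in vivo stride's pose space against ex vivo regions.

    Per axis: the fraction of in vivo tips inside the ex vivo region, the
    indices of frames falling outside, and (when summaries are supplied)
    the ratio of the in vivo range to the pooled ex vivo range (ex vivo
    pooled as min-of-mins to max-of-maxes).  ``null_pose_reachable`` asks
    whether the identity pose — each axis tip at its own basis vector —
    lies inside every ex vivo region.
    """
    inside_fraction, outside_frames = {}, {}
    for axis in AXES:
        region = exvivo_regions[axis]
        tips = invivo.tips(axis)
        inside = np.array([point_in_region(p, region) for p in tips])
        inside_fraction[axis] = float(np.mean(inside))
        outside_frames[axis] = [int(i) for i in np.nonzero(~inside)[0]]

    range_ratio = {}
    if invivo_summary is not None and exvivo_summaries:
        for axis in AXES:
            ex_max = max(s.axes[axis].max for s in exvivo_summaries)
            ex_min = min(s.axes[axis].min for s in exvivo_summaries)
            ex_range = ex_max - ex_min
            if ex_range > 0:
                range_ratio[axis] = invivo_summary.axes[axis].range / ex_range

    identity_tips = {"LAR": np.array([1.0, 0.0, 0.0]),
                     "ABAD": np.array([0.0, 1.0, 0.0]),
                     "FE": np.array([0.0, 0.0, 1.0])}
    null_ok = all(point_in_region(identity_tips[axis], exvivo_regions[axis])
                  for axis in AXES)
    return ComparisonReport(inside_fraction=inside_fraction,
                            outside_frames=outside_frames,
                            range_ratio=range_ratio,
                            null_pose_reachable=null_ok)
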