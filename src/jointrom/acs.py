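"""Anatomical coordinate systems (ACSs) from bone landmarks.

Salamander long bones have flat osseous ends capped with cartilage, so the
ACSs are built from points placed on the perimeters of the articular ends
rather than from surface primitives — except at the hip, where the roughly
spherical acetabula and the roughly cylindrical sacral vertebral body do
support primitive fits.

Per-bone rules:

* long bones — preliminary X (LAR) from the proximal to the distal perimeter
  mean; preliminary Z (FE) a line fit through the perimeter at the joint
  end; Y = X x Z; then one preliminary axis is recomputed so the triad is
  orthogonal.  Proximal femur and tibia/fibula keep the long axis
  (Z := X x Y); the distal femur keeps the FE line fit (X := Y x Z), because
  its distal surface is longest along FE.
* pelvis — Y (mediolateral) joins the two acetabular sphere centroids;
  X (anteroposterior) is the sacral cylinder axis with its yaw removed
  (projected perpendicular to Y), pointing caudally; Z = X x Y points up;
  origin midway between the centroids.
* acetabula — pelvis axes re-labelled per side so that in the null pose the
  femur extends laterally with hip X (LAR) pointing out of the socket and
  hip Z (FE) along the pelvis dorsoventral axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateGeometryError, MissingReferenceError, ValidationError

ACS_ATOL = 1e-9
#: Condition number above which a point cloud is treated as degenerate.
DEGENERACY_COND = 1e8


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("cannot normalise a zero vector")
    return v / n


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Perimeter and reference landmarks for one bone (mm)."""

    proximal_perimeter: np.ndarray
    distal_perimeter: np.ndarray
    reference_points: dict = field(default_factory=dict)
    bone: str = ""
    side: str = "right"

    def __post_init__(self) -> None:
        self.proximal_perimeter = np.atleast_2d(
            np.asarray(self.proximal_perimeter, dtype=float))
        self.distal_perimeter = np.atleast_2d(
            np.asarray(self.distal_perimeter, dtype=float))
        self.reference_points = {
            k: np.asarray(v, dtype=float) for k, v in self.reference_points.items()
        }


@dataclass(frozen=True)
class SpherePrimitive:
    center: np.ndarray
    radius: float
    rms_residual: float


@dataclass(frozen=True)
class CylinderPrimitive:
    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    rms_residual: float


@dataclass
class ACS:
    """Origin plus a right-handed orthonormal triad attached to a bone.

    For limb bones X = LAR, Y = ABAD, Z = FE; for the pelvis X is
    anteroposterior, Y mediolateral, Z dorsoventral.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    bone: str = ""
    side: str = "right"
    residuals: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.x_axis = np.asarray(self.x_axis, dtype=float)
        self.y_axis = np.asarray(self.y_axis, dtype=float)
        self.z_axis = np.asarray(self.z_axis, dtype=float)

    @property
    def rotation(self) -> np.ndarray:
        """World->ACS orientation with axes as columns."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])


# ---------------------------------------------------------------------------
# Primitive fits
# ---------------------------------------------------------------------------

def fit_line(points: np.ndarray, reference: np.ndarray | None = None):
    """Total-least-squares 3D line: (centroid, unit direction).

    Direction is the first principal axis of the cloud.  Its sign is chosen
    toward ``reference`` if given, else canonicalised lexicographically
    (first nonzero component positive).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(np.unique(pts, axis=0)) < 2:
        raise DegenerateGeometryError("line fit needs >= 2 distinct points")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    direction = vt[0]
    if reference is not None:
        if np.dot(direction, np.asarray(reference, dtype=float) - centroid) < 0:
            direction = -direction
    else:
        nz = np.nonzero(np.abs(direction) > 1e-12)[0][0]
        if direction[nz] < 0:
            direction = -direction
    return centroid, direction


def fit_sphere(points: np.ndarray) -> SpherePrimitive:
    """Least-squares sphere: algebraic fit then geometric refinement."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 4:
        raise DegenerateGeometryError("sphere fit needs >= 4 points")
    # Algebraic: ||p||^2 = 2 c.p + (r^2 - ||c||^2)
    a = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.sum(pts * pts, axis=1)
    if np.linalg.cond(a) > DEGENERACY_COND:
        raise DegenerateGeometryError("points are coplanar or otherwise degenerate")
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + center0 @ center0, 1e-12)))

    def resid(p):
        return np.linalg.norm(pts - p[:3], axis=1) - p[3]

    fit = least_squares(resid, np.append(center0, r0), method="lm")
    center, radius = fit.x[:3], float(fit.x[3])
    if radius <= 0:
        raise DegenerateGeometryError("sphere fit collapsed to nonpositive radius")
    rms = float(np.sqrt(np.mean(resid(fit.x) ** 2)))
    return SpherePrimitive(center=center, radius=radius, rms_residual=rms)


def _tangent_basis(d: np.ndarray):
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, helper))
    v = np.cross(d, u)
    return u, v


def fit_cylinder(points: np.ndarray,
                 caudal_reference: np.ndarray | None = None) -> CylinderPrimitive:
    """Least-squares circular cylinder.

    The axis is initialised from the cloud's first principal component and
    refined with nonlinear least squares (axis direction parameterised by
    two tilt angles around the initial axis, axis point by its in-plane
    offset).  The direction sign is chosen toward ``caudal_reference`` when
    supplied.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 6:
        raise DegenerateGeometryError("cylinder fit needs >= 6 points")
    centroid = pts.mean(axis=0)
    q = pts - centroid
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    if s[0] < 1e-9 or s[0] / max(s[1], 1e-300) > DEGENERACY_COND:
        raise DegenerateGeometryError("cloud has no cylindrical extent")
    d0 = vt[0]
    u0, v0 = _tangent_basis(d0)
    radial = q - np.outer(q @ d0, d0)
    r0 = float(np.mean(np.linalg.norm(radial, axis=1)))
    if r0 < 1e-9:
        raise DegenerateGeometryError("points are collinear, not cylindrical")

    def unpack(p):
        a, b, ox, oy, r = p
        d = _unit(d0 + a * u0 + b * v0)
        point = centroid + ox * u0 + oy * v0
        return point, d, r

    def resid(p):
        point, d, r = unpack(p)
        w = pts - point
        dist = np.linalg.norm(w - np.outer(w @ d, d), axis=1)
        return dist - r

    fit = least_squares(resid, np.array([0.0, 0.0, 0.0, 0.0, r0]), method="lm")
    point, d, r = unpack(fit.x)
    if r <= 0:
        raise DegenerateGeometryError("cylinder fit collapsed to nonpositive radius")
    if caudal_reference is not None:
        if np.dot(d, np.asarray(caudal_reference, dtype=float) - point) < 0:
            d = -d
    rms = float(np.sqrt(np.mean(resid(fit.x) ** 2)))
    return CylinderPrimitive(axis_point=point, axis_direction=d,
                             radius=float(r), rms_residual=rms)


# ---------------------------------------------------------------------------
# ACS construction
# ---------------------------------------------------------------------------

def _check_perimeter(pts: np.ndarray, label: str) -> None:
    if len(pts) < 3:
        raise DegenerateGeometryError(f"{label} perimeter needs >= 3 points")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError(f"{label} perimeter points are collinear")


def build_long_bone_acs(
    lm: LandmarkSet,
    mode: Literal["keep_long_axis", "keep_fe_axis"],
    end: Literal["proximal", "distal"],
) -> ACS:
    """Build a limb-bone ACS from its perimeter landmarks.

    ``end`` selects which articular perimeter carries the origin and the
    preliminary FE line fit.  ``mode`` selects which preliminary axis
    survives orthogonalisation: ``keep_long_axis`` (proximal femur,
    tibia/fibula) leaves X exactly along the long axis and recomputes
    Z = X x Y; ``keep_fe_axis`` (distal femur) leaves Z exactly along the
    perimeter line fit and recomputes X = Y x Z.

    Axis signs: X points proximal->distal; Z is oriented, and Y's sign
    follows, so that the 'ventral' reference point (``reference_points``,
    any key containing 'ventral' or 'flexor') lies on the negative-Y side —
    the flexor surface faces -Y, making positive Y abduction.  Without a
    reference the sign is canonicalised lexicographically and flagged in
    ``residuals['sign_canonicalised']``.
    """
    if mode not in ("keep_long_axis", "keep_fe_axis"):
        raise ValidationError(f"unknown mode {mode!r}")
    if end not in ("proximal", "distal"):
        raise ValidationError(f"unknown end {end!r}")
    _check_perimeter(lm.proximal_perimeter, "proximal")
    _check_perimeter(lm.distal_perimeter, "distal")

    mean_prox = lm.proximal_perimeter.mean(axis=0)
    mean_dist = lm.distal_perimeter.mean(axis=0)
    perimeter = lm.proximal_perimeter if end == "proximal" else lm.distal_perimeter
    origin = perimeter.mean(axis=0)

    x = _unit(mean_dist - mean_prox)  # preliminary LAR, along the long axis
    _, z = fit_line(perimeter)        # preliminary FE

    ref = None
    for key, p in lm.reference_points.items():
        if "ventral" in key or "flexor" in key:
            ref = p
            break
    flagged = False
    y = np.cross(x, z)
    if np.linalg.norm(y) < 1e-9:
        raise DegenerateGeometryError("long axis and FE line are parallel")
    y = _unit(y)
    if ref is not None:
        if np.dot(y, ref - origin) > 0:  # flexor side must face -Y
            y = -y
    else:
        nz = np.nonzero(np.abs(y) > 1e-12)[0][0]
        if y[nz] < 0:
            y = -y
        flagged = True

    if mode == "keep_long_axis":
        z = _unit(np.cross(x, y))
    else:
        # re-orthogonalise Y against the retained Z, then X = Y x Z
        y = _unit(y - np.dot(y, z) * z)
        x_new = np.cross(y, z)
        if np.dot(x_new, x) < 0:  # keep X pointing proximal->distal
            z = -z
            x_new = -x_new
        x = _unit(x_new)
    # exact right-handed closure
    if mode == "keep_long_axis":
        y = _unit(np.cross(z, x))
    acs = ACS(origin=origin, x_axis=x, y_axis=y, z_axis=z,
              bone=lm.bone, side=lm.side)
    if flagged:
        acs.residuals["sign_canonicalised"] = True
    acs.residuals.update(validate_acs(acs)["residuals"])
    return acs


def build_pelvis_and_acetabular_acs(
    left_acet: np.ndarray,
    right_acet: np.ndarray,
    sacral_body: np.ndarray,
    caudal_ref: np.ndarray,
):
    """Pelvis ACS plus per-side acetabular (hip) ACSs.

    Returns ``(pelvis, left_hip, right_hip)``.  Pelvis: Y mediolateral
    (left centroid -> right centroid), X anteroposterior (sacral cylinder
    axis with yaw removed, pointing caudally toward ``caudal_ref``),
    Z = X x Y pointing up, origin midway between the acetabular centroids.

    Hip ACSs re-label the pelvis axes so hip X (LAR) points laterally out
    of each socket and hip Z (FE) lies along the pelvis dorsoventral axis;
    hip Y completes the right-handed triad.  This fixed re-labelling is the
    convention under which the femoral ACS matches the acetabular ACS in
    the laterally-extended null pose.
    """
    caudal_ref = np.asarray(caudal_ref, dtype=float)
    sph_l = fit_sphere(left_acet)
    sph_r = fit_sphere(right_acet)
    cyl = fit_cylinder(sacral_body, caudal_reference=caudal_ref)

    sep = sph_r.center - sph_l.center
    if np.linalg.norm(sep) < 1e-9:
        raise DegenerateGeometryError("acetabular centroids coincide")
    y_pel = _unit(sep)
    # remove the yaw: project the sacral axis onto the plane perpendicular
    # to the mediolateral axis, keeping only its pitch
    x_pel = cyl.axis_direction - np.dot(cyl.axis_direction, y_pel) * y_pel
    if np.linalg.norm(x_pel) < 1e-9:
        raise DegenerateGeometryError("sacral axis parallel to mediolateral axis")
    x_pel = _unit(x_pel)
    origin = 0.5 * (sph_l.center + sph_r.center)
    if np.dot(x_pel, caudal_ref - origin) < 0:
        x_pel = -x_pel
    z_pel = _unit(np.cross(x_pel, y_pel))

    pelvis = ACS(origin=origin, x_axis=x_pel, y_axis=y_pel, z_axis=z_pel,
                 bone="pelvis",
                 residuals={"sphere_rms_left": sph_l.rms_residual,
                            "sphere_rms_right": sph_r.rms_residual,
                            "cylinder_rms": cyl.rms_residual})

    def hip(center, side):
        x = y_pel if side == "right" else -y_pel   # lateral, out of the socket
        z = z_pel                                   # FE along dorsoventral
        y = np.cross(z, x)                          # so that x cross y = z
        return ACS(origin=center, x_axis=x, y_axis=y, z_axis=z,
                   bone="acetabulum", side=side)

    return pelvis, hip(sph_l.center, "left"), hip(sph_r.center, "right")


def validate_acs(a: ACS, tol: float = ACS_ATOL) -> dict:
    """Orthogonality/unit-norm/handedness residuals and pass/fail at ``tol``."""
    res = {
        "xy_dot": float(abs(np.dot(a.x_axis, a.y_axis))),
        "yz_dot": float(abs(np.dot(a.y_axis, a.z_axis))),
        "xz_dot": float(abs(np.dot(a.x_axis, a.z_axis))),
        "x_norm_err": float(abs(np.linalg.norm(a.x_axis) - 1.0)),
        "y_norm_err": float(abs(np.linalg.norm(a.y_axis) - 1.0)),
        "z_norm_err": float(abs(np.linalg.norm(a.z_axis) - 1.0)),
        "handedness_err": float(
            np.max(np.abs(np.cross(a.x_axis, a.y_axis) - a.z_axis))),
    }
    return {"passed": all(v <= tol for v in res.values()),
            "tolerance": tol, "residuals": res}


def gram_schmidt_repair(a: ACS) -> ACS:
    """Re-orthonormalise a slightly skewed triad (X kept, Y projected)."""
    x = _unit(a.x_axis)
    y = _unit(a.y_axis - np.dot(a.y_axis, x) * x)
    z = np.cross(x, y)
    return ACS(origin=a.origin.copy(), x_axis=x, y_axis=y, z_axis=z,
               bone=a.bone, side=a.side)
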