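"""Rotation representations and the ZYX Euler machinery.

Joint rotations are expressed as proper rotation matrices of a distal
anatomical coordinate system (ACS) relative to a proximal one.  The Euler
decomposition is intrinsic Z-then-Y-then-X on column vectors,

    R = Rz(fe) @ Ry(abad) @ Rx(lar),

in degrees, with Z = flexion-extension (FE), Y = abduction-adduction (ABAD)
and X = long-axis rotation (LAR) — the axis ordering used throughout
XROMM-style joint studies, with the Z axis assigned to the axis of greatest
expected motion.  The null (reference) pose is the identity: distal and
proximal ACSs aligned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidAngleError, InvalidRotationError, ValidationError

#: Tolerance for orthonormality / unit-determinant checks.
ROTATION_ATOL = 1e-9
#: |cos(abad)| below this is treated as gimbal lock.
GIMBAL_LOCK_TOL = 1e-8

AXIS_NAMES = ("fe_z", "abad_y", "lar_x")


# ---------------------------------------------------------------------------
# Rotation matrices
# ---------------------------------------------------------------------------

def check_rotation(m: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Validate that ``m`` is a proper rotation; return it as float array.

    Raises
    ------
    InvalidRotationError
        If ``m`` is not 3x3, not orthonormal within ``atol``, or has
        determinant != +1 within ``atol``.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3) or not np.all(np.isfinite(m)):
        raise InvalidRotationError("expected a finite 3x3 matrix")
    if not np.allclose(m.T @ m, np.eye(3), atol=atol):
        raise InvalidRotationError("matrix is not orthonormal")
    if abs(np.linalg.det(m) - 1.0) > atol:
        raise InvalidRotationError("matrix is not a proper rotation (det != +1)")
    return m


@dataclass(frozen=True)
class EulerTriple:
    """ZYX Euler angles in degrees: (FE about Z, ABAD about Y, LAR about X)."""

    fe_z: float
    abad_y: float
    lar_x: float

    def __post_init__(self) -> None:
        for name in AXIS_NAMES:
            if not math.isfinite(getattr(self, name)):
                raise InvalidAngleError(f"{name} is not finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.fe_z, self.abad_y, self.lar_x], dtype=float)


@dataclass(frozen=True)
class JointConvention:
    """Axis-direction labelling for a joint/side, defining positive rotations."""

    joint: str
    side: str = "right"
    positive_z: str = ""
    positive_y: str = "abduction"
    positive_x: str = "external rotation"
    null_pose: str = ""

    def __post_init__(self) -> None:
        if self.joint not in ("hip", "knee"):
            raise ValidationError(f"unknown joint {self.joint!r}")
        if self.side not in ("left", "right"):
            raise ValidationError(f"unknown side {self.side!r}")
        if not self.positive_z:
            object.__setattr__(
                self,
                "positive_z",
                "extension (retraction)" if self.joint == "hip" else "flexion",
            )
        if not self.null_pose:
            object.__setattr__(
                self,
                "null_pose",
                "distal and proximal ACSs aligned, limb extended laterally",
            )


HIP_CONVENTION = JointConvention(joint="hip")
KNEE_CONVENTION = JointConvention(joint="knee")


def _rz(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rx(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def euler_to_matrix(e: EulerTriple | Sequence[float]) -> np.ndarray:
    """Compose R = Rz(fe) @ Ry(abad) @ Rx(lar), angles in degrees."""
    if not isinstance(e, EulerTriple):
        e = EulerTriple(*e)
    return _rz(e.fe_z) @ _ry(e.abad_y) @ _rx(e.lar_x)


def euler_to_matrix_batch(angles: np.ndarray) -> np.ndarray:
    """Vectorised euler_to_matrix for an (n, 3) array of (fe, abad, lar) deg."""
    a = np.radians(np.asarray(angles, dtype=float))
    if not np.all(np.isfinite(a)):
        raise InvalidAngleError("non-finite Euler angle in batch")
    cf, sf = np.cos(a[:, 0]), np.sin(a[:, 0])
    cb, sb = np.cos(a[:, 1]), np.sin(a[:, 1])
    cl, sl = np.cos(a[:, 2]), np.sin(a[:, 2])
    r = np.empty((len(a), 3, 3))
    r[:, 0, 0] = cf * cb
    r[:, 0, 1] = cf * sb * sl - sf * cl
    r[:, 0, 2] = cf * sb * cl + sf * sl
    r[:, 1, 0] = sf * cb
    r[:, 1, 1] = sf * sb * sl + cf * cl
    r[:, 1, 2] = sf * sb * cl - cf * sl
    r[:, 2, 0] = -sb
    r[:, 2, 1] = cb * sl
    r[:, 2, 2] = cb * cl
    return r


def _canonical_deg(x: float) -> float:
    """Wrap to (-180, 180], ties at ±180 mapped to +180."""
    y = math.remainder(x, 360.0)
    return 180.0 if y == -180.0 else y


def matrix_to_euler(r: np.ndarray, atol: float = 1e-6) -> EulerTriple:
    """Decompose a proper rotation into ZYX Euler angles (degrees).

    The ABAD (Y) angle is restricted to [-90, 90].  At gimbal lock
    (|cos abad| < GIMBAL_LOCK_TOL) LAR is set to 0 and the residual
    rotation is folded into FE.
    """
    r = check_rotation(r, atol=atol)
    sb = -r[2, 0]
    sb = min(1.0, max(-1.0, sb))
    abad = math.degrees(math.asin(sb))
    if 1.0 - abs(sb) < GIMBAL_LOCK_TOL:
        # R depends only on fe -/+ lar; convention: lar = 0
        if sb > 0:  # abad = +90: third column = (cos fe, sin fe, 0)
            fe = math.degrees(math.atan2(r[1, 2], r[0, 2]))
        else:  # abad = -90: third column = (-cos fe, -sin fe, 0)
            fe = math.degrees(math.atan2(-r[1, 2], -r[0, 2]))
        return EulerTriple(_canonical_deg(fe), abad, 0.0)
    fe = math.degrees(math.atan2(r[1, 0], r[0, 0]))
    lar = math.degrees(math.atan2(r[2, 1], r[2, 2]))
    return EulerTriple(_canonical_deg(fe), abad, _canonical_deg(lar))


def matrix_to_euler_batch(r: np.ndarray) -> np.ndarray:
    """Vectorised ZYX decomposition of an (n, 3, 3) stack -> (n, 3) degrees.

    Uses the same gimbal-lock convention as :func:`matrix_to_euler`.
    """
    r = np.asarray(r, dtype=float)
    sb = np.clip(-r[:, 2, 0], -1.0, 1.0)
    abad = np.degrees(np.arcsin(sb))
    fe = np.degrees(np.arctan2(r[:, 1, 0], r[:, 0, 0]))
    lar = np.degrees(np.arctan2(r[:, 2, 1], r[:, 2, 2]))
    lock = 1.0 - np.abs(sb) < GIMBAL_LOCK_TOL
    if np.any(lock):
        sign = np.sign(sb[lock])
        fe_lock = np.degrees(
            np.arctan2(sign * r[lock, 1, 2], sign * r[lock, 0, 2])
        )
        fe[lock] = fe_lock
        lar[lock] = 0.0
    return np.column_stack([fe, abad, lar])


# ---------------------------------------------------------------------------
# Relative motion, mirroring, metrics
# ---------------------------------------------------------------------------

def relative_rotation(r_prox: np.ndarray, r_dist: np.ndarray) -> np.ndarray:
    """Rotation of the distal ACS expressed in the proximal ACS: R_p^T R_d.

    Identity iff the two frames are aligned (the null pose).
    """
    r_prox = check_rotation(r_prox)
    r_dist = check_rotation(r_dist)
    return r_prox.T @ r_dist


_MIRROR = np.diag([1.0, -1.0, 1.0])


def mirror_pose(r: np.ndarray) -> np.ndarray:
    """Reflect a pose across the proximal-frame X-Z plane: M @ R @ M.

    M = diag(1, -1, 1) negates the mediolateral (Y) direction; in Euler
    terms (fe, abad, lar) -> (-fe, abad, -lar).  Used to convert left-side
    joint data to right-side conventions.  Involution: applying twice is a
    no-op.
    """
    r = check_rotation(r)
    return _MIRROR @ r @ _MIRROR


def geodesic_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angular distance in degrees between two rotations or two unit vectors.

    For rotations: the rotation angle of a^T b via the trace formula.
    For unit vectors: arccos of the clamped dot product.  Both in [0, 180].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("geodesic_angle requires inputs of the same kind")
    if a.shape == (3, 3):
        a = check_rotation(a)
        b = check_rotation(b)
        c = (np.trace(a.T @ b) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))
    if a.shape == (3,):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-12 or nb < 1e-12:
            raise ValidationError("zero vector has no direction")
        c = float(np.dot(a / na, b / nb))
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))
    raise ValidationError("expected two 3x3 rotations or two 3-vectors")


# ---------------------------------------------------------------------------
# Pose sequences
# ---------------------------------------------------------------------------

@dataclass
class PoseSequence:
    """Time series of relative rotations (distal ACS in the proximal ACS).

    ``frames`` is an (n, 3, 3) stack of proper rotations, ``times`` seconds
    (strictly increasing), ``rate_hz`` the nominal capture rate (ex vivo
    trials were captured at 30 Hz).  ``meta`` carries specimen id, joint,
    side, context ('ex_vivo' or 'in_vivo'), trial id and sweep label.
    """

    frames: np.ndarray
    times: np.ndarray
    rate_hz: float = 30.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (3, 3):
            raise ValidationError("frames must be an (n, 3, 3) stack")
        n = len(self.frames)
        if n < 1 or len(self.times) != n:
            raise ValidationError("need len(frames) == len(times) >= 1")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if not self.rate_hz > 0:
            raise ValidationError("rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_euler(
        cls,
        angles: np.ndarray | Iterable[Sequence[float]],
        rate_hz: float = 30.0,
        meta: dict | None = None,
    ) -> "PoseSequence":
        """Build a sequence from (n, 3) Euler triples, frames at 1/rate_hz."""
        angles = np.atleast_2d(np.asarray(list(angles), dtype=float))
        frames = euler_to_matrix_batch(angles)
        times = np.arange(len(frames)) / rate_hz
        return cls(frames=frames, times=times, rate_hz=rate_hz, meta=dict(meta or {}))

    def to_euler(self) -> np.ndarray:
        """Per-frame ZYX Euler angles, (n, 3) degrees (FE, ABAD, LAR)."""
        return matrix_to_euler_batch(self.frames)

    def mirrored(self) -> "PoseSequence":
        """Left/right mirrored copy (side metadata flipped)."""
        frames = _MIRROR[None] @ self.frames @ _MIRROR[None]
        meta = dict(self.meta)
        if meta.get("side") in ("left", "right"):
            meta["side"] = "right" if meta["side"] == "left" else "left"
        meta["mirrored"] = not self.meta.get("mirrored", False)
        return PoseSequence(frames=frames, times=self.times.copy(),
                            rate_hz=self.rate_hz, meta=meta)

    def validate(self, atol: float = 1e-6) -> None:
        """Check every frame is a proper rotation; raise naming the frame."""
        for i, f in enumerate(self.frames):
            try:
                check_rotation(f, atol=atol)
            except InvalidRotationError as exc:
                raise InvalidRotationError(f"frame {i}: {exc}") from exc
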