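"""Synthetic joints, sweep trials, strides, landmarks and marker data.

The generators stand in for the specimens: a :class:`JointLimitModel`
defines a smooth feasible set in ZYX Euler space — a coupled ellipsoid,
the simplest shape whose per-axis extremes depend on the rotations about
the other two axes (interaction of degrees of freedom) — with a passive
torque that is zero inside the set and rises linearly beyond its
boundary.  The ex vivo simulator drives hierarchical axis sweeps bounded
by a torque threshold, mimicking the rig protocol; the in vivo simulator
produces one periodic stride cycle inside the feasible set.  Landmark and
marker generators provide ground-truth fixtures for the ACS and pose
recovery stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .acs import LandmarkSet
from .errors import (
    InfeasibleStrideError,
    InsufficientMarkersError,
    InvalidModelError,
    ValidationError,
)
from .kinematics import PoseSequence, euler_to_matrix_batch
from .markers import MarkerFrame, MarkerTemplate

#: Letter -> Euler column (FE, ABAD, LAR).
_AXIS_OF_LETTER = {"F": 0, "A": 1, "L": 2}
SWEEP_SEQUENCES = ("FAL", "FLA", "AFL", "ALF", "LFA", "LAF")
PLANAR_SEQUENCES = ("F", "A", "L")
_PLANAR_LABEL = {"F": "planar-FE", "A": "planar-ABAD", "L": "planar-LAR"}


# ---------------------------------------------------------------------------
# Joint-limit model
# ---------------------------------------------------------------------------

@dataclass
class JointLimitModel:
    """Coupled-ellipsoid feasible set with a boundary torque spring.

    The feasible set is ``{e : || S C (e - center) || <= 1}`` with
    ``S = diag(1/semi_axes)`` and ``C`` a well-conditioned shear (the DoF
    coupling).  Passive torque is zero inside the set and
    ``stiffness * (distance in degrees beyond the boundary along the ray
    from the centre)`` outside; the sweep protocol stops where torque
    would reach ``torque_threshold``.
    """

    center: np.ndarray                     # (fe, abad, lar) degrees
    semi_axes: np.ndarray                  # degrees
    coupling: np.ndarray = field(default_factory=lambda: np.eye(3))
    torque_stiffness: float = 10.0         # N*mm per degree beyond boundary
    torque_threshold: float = 10.0         # N*mm

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float).reshape(3)
        self.coupling = np.asarray(self.coupling, dtype=float).reshape(3, 3)
        if np.any(self.semi_axes <= 0):
            raise InvalidModelError("semi_axes must be positive")
        if np.linalg.cond(self.coupling) > 1e6:
            raise InvalidModelError("coupling matrix is ill-conditioned")
        if self.torque_stiffness <= 0:
            raise InvalidModelError("torque_stiffness must be positive")
        if self.torque_threshold < 0:
            raise InvalidModelError("torque_threshold must be >= 0")
        s = np.diag(1.0 / self.semi_axes)
        sc = s @ self.coupling
        self._quad = sc.T @ sc            # M: feasible iff d^T M d <= 1

    # -- geometry -----------------------------------------------------------

    def squared_level(self, e: np.ndarray) -> np.ndarray:
        """d^T M d for one pose or an (n, 3) batch (<= 1 inside)."""
        d = np.atleast_2d(np.asarray(e, dtype=float)) - self.center
        return np.einsum("ni,ij,nj->n", d, self._quad, d)

    def contains(self, e: np.ndarray, shrink: float = 0.0) -> np.ndarray:
        """Membership, optionally of the set shrunk by a radial margin."""
        return self.squared_level(e) <= (1.0 - shrink) ** 2

    def torque(self, e: np.ndarray) -> np.ndarray:
        """Passive torque (N*mm) for one pose or an (n, 3) batch."""
        e2 = np.atleast_2d(np.asarray(e, dtype=float))
        g = np.sqrt(np.maximum(self.squared_level(e2), 0.0))
        r = np.linalg.norm(e2 - self.center, axis=1)
        exceed = np.where(g > 1.0, r * (1.0 - 1.0 / np.maximum(g, 1e-12)), 0.0)
        return self.torque_stiffness * exceed

    def axis_extrema(self) -> np.ndarray:
        """Analytic per-axis (min, max) of the feasible set, (3, 2) degrees.

        The support of the ellipsoid ``{d : d^T M d <= 1}`` along axis i is
        ``sqrt((M^-1)_ii)``.
        """
        minv = np.linalg.inv(self._quad)
        half = np.sqrt(np.diag(minv))
        return np.column_stack([self.center - half, self.center + half])

    def conditional_interval(self, axis: int, fixed: dict) -> tuple | None:
        """Feasible interval of one Euler axis with the other two fixed.

        ``fixed`` maps the other axis indices to absolute angles.  Returns
        (lo, hi) in degrees, or None when empty.
        """
        m = self._quad
        d = np.zeros(3)
        for j, val in fixed.items():
            d[j] = val - self.center[j]
        a = m[axis, axis]
        b = sum(m[axis, j] * d[j] for j in fixed)
        k = sum(d[i] * m[i, j] * d[j] for i in fixed for j in fixed)
        disc = b * b - a * (k - 1.0)
        if disc < 0:
            return None
        root = math.sqrt(disc)
        lo = self.center[axis] + (-b - root) / a
        hi = self.center[axis] + (-b + root) / a
        return lo, hi

    def slice_nonempty(self, fixed: dict) -> bool:
        """Whether any assignment of the free axes is feasible.

        Minimises the quadratic level over the free coordinates (Schur
        complement) at the fixed ones.
        """
        fixed_idx = sorted(fixed)
        free_idx = [i for i in range(3) if i not in fixed]
        d_f = np.array([fixed[i] - self.center[i] for i in fixed_idx])
        m = self._quad
        if not free_idx:
            return float(d_f @ m[np.ix_(fixed_idx, fixed_idx)] @ d_f) <= 1.0
        mff = m[np.ix_(fixed_idx, fixed_idx)]
        mfr = m[np.ix_(fixed_idx, free_idx)]
        mrr = m[np.ix_(free_idx, free_idx)]
        schur = mff - mfr @ np.linalg.solve(mrr, mfr.T)
        return float(d_f @ schur @ d_f) <= 1.0


def hip_like_model(**overrides) -> JointLimitModel:
    """Synthetic hip: broad motion about all three axes.

    The centre sits at strong internal rotation (LAR well below zero), so
    the null pose is outside the feasible set — as observed in real
    salamander hips, every attainable pose involves some internal
    rotation.
    """
    kw = dict(center=(-25.0, 0.0, -75.0), semi_axes=(52.0, 45.0, 52.0),
              coupling=np.array([[1.0, 0.20, 0.10],
                                 [0.0, 1.00, 0.15],
                                 [0.0, 0.00, 1.00]]))
    kw.update(overrides)
    return JointLimitModel(**kw)


def knee_like_model(**overrides) -> JointLimitModel:
    """Synthetic knee: FE-dominant, centred at substantial flexion.

    0 degrees of flexion (the straightened null pose) is infeasible; ABAD
    and LAR ranges are similar to each other and much smaller than FE.
    """
    kw = dict(center=(65.0, 0.0, 0.0), semi_axes=(58.0, 25.0, 30.0),
              coupling=np.array([[1.0, 0.15, 0.10],
                                 [0.0, 1.00, 0.12],
                                 [0.0, 0.00, 1.00]]))
    kw.update(overrides)
    return JointLimitModel(**kw)


# ---------------------------------------------------------------------------
# Ex vivo sweep protocol
# ---------------------------------------------------------------------------

@dataclass
class SweepSpec:
    """Hierarchical sweep protocol parameters.

    ``sequence`` is one of the six interaction orders (first letter =
    innermost, i.e. most frequently swept axis) or a single letter for a
    planar reference trial.  ``steps`` are per-axis increments in degrees
    in (FE, ABAD, LAR) order; capture runs at ``rate_hz``.
    """

    sequence: str = "FAL"
    steps: tuple = (3.0, 6.0, 6.0)
    rate_hz: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sequence not in SWEEP_SEQUENCES + PLANAR_SEQUENCES:
            raise ValidationError(f"unknown sweep sequence {self.sequence!r}")
        if any(s <= 0 for s in self.steps):
            raise ValidationError("step sizes must be positive")


def _stepped_values(model, axis, fixed, step):
    """Grid values along ``axis`` stepping outward until the slice empties."""
    out_pos, out_neg = [], []
    base = model.center[axis]
    k = 0
    while True:
        k += 1
        v = base + k * step
        if not model.slice_nonempty({**fixed, axis: v}):
            break
        out_pos.append(v)
    k = 0
    while True:
        k += 1
        v = base - k * step
        if not model.slice_nonempty({**fixed, axis: v}):
            break
        out_neg.append(v)
    return out_neg[::-1] + [base] + out_pos


def _inner_sweep(model, axis, fixed, step):
    """Torque-thresholded sweep along the innermost axis (ascending).

    Starts at the midpoint of the conditional feasible interval and
    extends outward in both directions while simulated torque stays
    strictly below the threshold, so with threshold 0 nothing but the
    global centre pose is ever emitted.
    """
    interval = model.conditional_interval(axis, fixed)
    if interval is None:
        return []
    mid = 0.5 * (interval[0] + interval[1])

    def pose_at(v):
        e = model.center.copy()
        for j, val in fixed.items():
            e[j] = val
        e[axis] = v
        return e

    tau = model.torque_threshold

    def emitted(v):
        e = pose_at(v)
        if float(model.torque(e)[0]) < tau:
            return True
        return bool(np.allclose(e, model.center))

    if not emitted(mid):
        return []
    values = [mid]
    v = mid + step
    while emitted(v):
        values.append(v)
        v += step
    v = mid - step
    left = []
    while emitted(v):
        left.append(v)
        v -= step
    values = left[::-1] + values
    return [pose_at(v) for v in values]


def _smooth_transitions(angles: np.ndarray, max_step: float) -> np.ndarray:
    """Insert interpolated frames where consecutive poses are far apart.

    Models the operator repositioning the handle between sweep rows; the
    feasible set (and every torque sublevel set) is convex, so linear
    interpolation in Euler space never leaves it.
    """
    if len(angles) < 2:
        return angles
    out = [angles[0]]
    for prev, cur in zip(angles[:-1], angles[1:]):
        gap = float(np.linalg.norm(cur - prev))
        n_insert = int(math.ceil(gap / max_step)) - 1
        for k in range(1, n_insert + 1):
            out.append(prev + (cur - prev) * k / (n_insert + 1))
        out.append(cur)
    return np.asarray(out)


def simulate_exvivo_trial(model: JointLimitModel, spec: SweepSpec):
    """Simulate one torque-thresholded ex vivo trial.

    Interaction sequences sweep the innermost axis through its full
    conditional range, then increment the middle axis and repeat, then the
    outermost, until the rotation limits about each are reached.  When an
    outer axis is incremented the inner sweep restarts from the midpoint
    of its new conditional interval, and traversal is boustrophedon, so
    consecutive frames remain continuous.  Planar specs sweep a single
    axis with the other two held at the centre pose.

    Returns ``(PoseSequence, torque)`` with one torque value (N*mm) per
    emitted 30 Hz frame; all emitted torques are below the threshold.
    """
    seq = spec.sequence
    poses: list = []
    if len(seq) == 1:
        axis = _AXIS_OF_LETTER[seq]
        others = {j: model.center[j] for j in range(3) if j != axis}
        step = spec.steps[axis]
        poses = _inner_sweep(model, axis, others, step)
        label = _PLANAR_LABEL[seq]
    else:
        inner, mid, outer = (_AXIS_OF_LETTER[ch] for ch in seq)
        outer_vals = _stepped_values(model, outer, {}, spec.steps[outer])
        for oi, ov in enumerate(outer_vals):
            mid_vals = _stepped_values(model, mid, {outer: ov}, spec.steps[mid])
            if oi % 2:
                mid_vals = mid_vals[::-1]
            for mi, mv in enumerate(mid_vals):
                row = _inner_sweep(model, inner, {outer: ov, mid: mv},
                                   spec.steps[inner])
                if (mi + oi) % 2:
                    row = row[::-1]
                poses.extend(row)
        label = seq
    if not poses:
        raise InvalidModelError("sweep emitted no poses; model/spec mismatch")
    angles = _smooth_transitions(np.asarray(poses), max(spec.steps))
    torque = model.torque(angles)
    ps = PoseSequence.from_euler(
        angles, rate_hz=spec.rate_hz,
        meta={"context": "ex_vivo", "sweep": label, "seed": spec.seed})
    return ps, torque


def simulate_all_sequences(model: JointLimitModel, steps=(3.0, 6.0, 6.0),
                           rate_hz: float = 30.0, seed: int = 0):
    """One trial per interaction sequence (the pooled ex vivo protocol)."""
    return [simulate_exvivo_trial(
        model, SweepSpec(sequence=s, steps=steps, rate_hz=rate_hz, seed=seed))[0]
        for s in SWEEP_SEQUENCES]


# ---------------------------------------------------------------------------
# In vivo stride
# ---------------------------------------------------------------------------

@dataclass
class StrideSpec:
    """One periodic stride cycle as per-axis sinusoids.

    ``mean``/``amplitude``/``phase`` are per axis in (FE, ABAD, LAR) order
    (degrees; phase in radians).  The whole trajectory must stay inside
    the joint-limit model's feasible set shrunk by ``margin`` (a radial
    fraction).  ``noise_deg`` adds seeded Gaussian jitter.
    """

    n_frames: int = 401
    mean: tuple = (0.0, 0.0, 0.0)
    amplitude: tuple = (30.0, 10.0, 20.0)
    phase: tuple = (0.0, 1.57, 3.14)
    margin: float = 0.05
    noise_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")


def simulate_stride(model: JointLimitModel, spec: StrideSpec) -> PoseSequence:
    """Generate one in vivo stride cycle inside the feasible set.

    401 frames (default) spanning exactly one period, so the first and
    last poses coincide.  Raises :class:`InfeasibleStrideError` if any
    frame leaves the margin-shrunken feasible set.
    """
    t = np.linspace(0.0, 1.0, spec.n_frames)
    mean = np.asarray(spec.mean, dtype=float)
    amp = np.asarray(spec.amplitude, dtype=float)
    phase = np.asarray(spec.phase, dtype=float)
    angles = mean[None, :] + amp[None, :] * np.sin(
        2.0 * math.pi * t[:, None] + phase[None, :])
    if spec.noise_deg > 0:
        rng = np.random.default_rng(spec.seed)
        angles = angles + rng.normal(0.0, spec.noise_deg, angles.shape)
    ok = model.contains(angles, shrink=spec.margin)
    if not np.all(ok):
        bad = int(np.nonzero(~ok)[0][0])
        raise InfeasibleStrideError(
            f"stride frame {bad} leaves the feasible set (margin {spec.margin})")
    return PoseSequence.from_euler(
        angles, rate_hz=30.0,
        meta={"context": "in_vivo", "sweep": "stride", "seed": spec.seed})


def default_hip_stride(model: JointLimitModel | None = None) -> StrideSpec:
    """Walking-like hip stride for :func:`hip_like_model`.

    FE uses most of its feasible range, ABAD roughly a third of its ex
    vivo range, LAR intermediate — the qualitative in vivo pattern.
    """
    if model is None:
        model = hip_like_model()
    return StrideSpec(mean=tuple(model.center),
                      amplitude=(38.0, 13.0, 28.0),
                      phase=(0.0, 1.3, 2.4))


def default_knee_stride(model: JointLimitModel | None = None) -> StrideSpec:
    """Walking-like knee stride for :func:`knee_like_model` (FE-dominant)."""
    if model is None:
        model = knee_like_model()
    return StrideSpec(mean=tuple(model.center),
                      amplitude=(45.0, 8.0, 10.0),
                      phase=(0.0, 0.9, 2.1))


# ---------------------------------------------------------------------------
# Landmark and marker fixtures
# ---------------------------------------------------------------------------

def _ellipse_ring(n, a, b, rng=None, noise=0.0):
    th = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    pts = np.column_stack([np.zeros(n), a * np.cos(th), b * np.sin(th)])
    if noise > 0:
        pts = pts + rng.normal(0.0, noise, pts.shape)
    return pts


def synth_landmarks(bone: str = "long_bone", length: float = 20.0,
                    prox_radii=(2.0, 3.0), dist_radii=(1.5, 2.5),
                    n_perimeter: int = 24, noise: float = 0.0,
                    rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    seed: int = 0):
    """Generate landmark fixtures with known ground-truth ACSs.

    ``long_bone``: perimeter ellipses (major axis along z, so the FE line
    fit is z) at both ends of a bone lying along +x, a ventral reference
    point on the -y side, optional Gaussian noise, and an optional rigid
    motion applied to everything.  Returns ``(LandmarkSet, truth)`` where
    ``truth`` maps 'proximal'/'distal' to dicts with origin and axes.

    ``pelvis``: two acetabular sphere caps (centres +/-5 mm along y), a
    sacral cylinder with a pitched axis, and a caudal reference point.
    Returns ``(point_sets, truth)``.
    """
    rng = np.random.default_rng(seed)
    r = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)

    def move(pts):
        return np.atleast_2d(pts) @ r.T + t

    if bone == "long_bone":
        prox = _ellipse_ring(n_perimeter, *prox_radii, rng=rng, noise=noise)
        dist = _ellipse_ring(n_perimeter, *dist_radii, rng=rng, noise=noise)
        dist = dist + np.array([length, 0.0, 0.0])
        ventral = np.array([length / 2.0, -max(prox_radii), 0.0])
        lm = LandmarkSet(proximal_perimeter=move(prox),
                         distal_perimeter=move(dist),
                         reference_points={"ventral_femur": move(ventral)[0]},
                         bone="long_bone")
        truth = {}
        for end, ring in (("proximal", prox), ("distal", dist)):
            truth[end] = {
                "origin": move(ring.mean(axis=0))[0],
                "x_axis": r @ np.array([1.0, 0.0, 0.0]),
                "y_axis": r @ np.array([0.0, 1.0, 0.0]),
                "z_axis": r @ np.array([0.0, 0.0, 1.0]),
            }
        return lm, truth

    if bone == "pelvis":
        def sphere_cap(center, radius=2.0, n=200):
            u = rng.uniform(0.35, 1.0, n)       # upper cap, non-coplanar
            phi = rng.uniform(0.0, 2.0 * math.pi, n)
            s = np.sqrt(1.0 - u * u)
            pts = center + radius * np.column_stack(
                [s * np.cos(phi), s * np.sin(phi), u])
            if noise > 0:
                pts = pts + rng.normal(0.0, noise, pts.shape)
            return pts

        pitch = math.radians(10.0)
        axis = np.array([-math.cos(pitch), 0.0, -math.sin(pitch)])
        h = rng.uniform(-4.0, 4.0, 300)
        phi = rng.uniform(0.0, 2.0 * math.pi, 300)
        u_b, v_b = np.array([0.0, 1.0, 0.0]), np.cross(axis, [0.0, 1.0, 0.0])
        sac_center = np.array([8.0, 0.0, 2.0])
        sacral = (sac_center + np.outer(h, axis)
                  + 1.2 * (np.outer(np.cos(phi), u_b) + np.outer(np.sin(phi), v_b)))
        if noise > 0:
            sacral = sacral + rng.normal(0.0, noise, sacral.shape)
        left_c = np.array([0.0, -5.0, 0.0])
        right_c = np.array([0.0, 5.0, 0.0])
        caudal = np.array([-15.0, 0.0, 0.0])
        sets = {
            "left_acet": move(sphere_cap(left_c)),
            "right_acet": move(sphere_cap(right_c)),
            "sacral_body": move(sacral),
            "caudal_ref": move(caudal)[0],
        }
        x_pel = np.array([-math.cos(pitch), 0.0, -math.sin(pitch)])
        x_pel = x_pel - (x_pel @ np.array([0.0, 1.0, 0.0])) * np.array([0.0, 1.0, 0.0])
        x_pel /= np.linalg.norm(x_pel)
        truth = {
            "origin": move(0.5 * (left_c + right_c))[0],
            "x_axis": r @ x_pel,
            "y_axis": r @ np.array([0.0, 1.0, 0.0]),
            "z_axis": r @ np.cross(x_pel, [0.0, 1.0, 0.0]),
            "left_center": move(left_c)[0],
            "right_center": move(right_c)[0],
        }
        return sets, truth

    raise ValidationError(f"unknown bone kind {bone!r}")


def default_marker_template() -> MarkerTemplate:
    """Asymmetric 7-marker rigid tree (mm), like the rig handle."""
    pts = np.array([
        [0.0, 0.0, 0.0],
        [30.0, 0.0, 0.0],
        [0.0, 25.0, 0.0],
        [0.0, 0.0, 20.0],
        [22.0, 18.0, 5.0],
        [-15.0, 10.0, 12.0],
        [10.0, -12.0, 18.0],
    ])
    return MarkerTemplate(marker_ids=[f"m{i}" for i in range(1, 8)],
                          reference_positions=pts)


def synth_marker_trial(template: MarkerTemplate, seq: PoseSequence,
                       noise_mm: float = 0.0, seed: int = 0,
                       translation: np.ndarray | None = None):
    """Marker trajectories of a rigid tree following a pose sequence.

    Each frame's markers are the template rotated by that frame (plus an
    optional constant translation) with additive Gaussian noise.  The
    round trip through :func:`jointrom.markers.pose_from_markers`
    recovers the sequence up to noise.
    """
    if len(template.reference_positions) < 3:
        raise InsufficientMarkersError("template needs >= 3 markers")
    rng = np.random.default_rng(seed)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    frames = []
    for i in range(len(seq)):
        pos = template.reference_positions @ seq.frames[i].T + t
        if noise_mm > 0:
            pos = pos + rng.normal(0.0, noise_mm, pos.shape)
        frames.append(MarkerFrame(time=float(seq.times[i]), positions=pos))
    return frames
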