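"""Rigid pose recovery from motion-capture marker trees and trial QC.

The ex vivo rig moves the distal bone with a handle carrying a 7-marker
rigid tree.  Each capture frame is converted to a rigid transform by a
closed-form Kabsch (SVD) fit against the marker template, then chained
through the marker->plate and plate->bone-ACS calibration transforms to
express the bone in world space.  Quality control follows the protocol's
discard rules: trials whose pose trace "jumps" discontinuously are dropped,
and a specimen counts as sufficiently sampled only with all three planar
trials plus at least two surviving interaction-of-degrees-of-freedom
trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InsufficientMarkersError,
    InvalidTransformError,
    MissingLabelError,
)
from .kinematics import PoseSequence, check_rotation, geodesic_angle

PLANAR_LABELS = ("planar-FE", "planar-ABAD", "planar-LAR")
INTERACTION_LABELS = ("FAL", "FLA", "AFL", "ALF", "LFA", "LAF")

#: Default per-frame jump threshold (degrees) between consecutive 30 Hz frames.
DEFAULT_JUMP_DEG = 15.0


@dataclass
class MarkerTemplate:
    """Reference marker positions (mm) in the rigid-body frame."""

    marker_ids: list
    reference_positions: np.ndarray

    def __post_init__(self) -> None:
        self.reference_positions = np.atleast_2d(
            np.asarray(self.reference_positions, dtype=float))
        if len(self.marker_ids) != len(self.reference_positions):
            raise DegenerateGeometryError("ids and positions differ in length")
        _require_noncollinear(self.reference_positions)


@dataclass
class MarkerFrame:
    """One capture frame: per-marker world positions plus visibility flags."""

    time: float
    positions: np.ndarray
    visibility: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.visibility is None:
            self.visibility = np.all(np.isfinite(self.positions), axis=1)
        else:
            self.visibility = np.asarray(self.visibility, dtype=bool)


@dataclass
class RigidTransform:
    """x' = rotation @ x + translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        try:
            self.rotation = check_rotation(self.rotation)
        except Exception as exc:
            raise InvalidTransformError(str(exc)) from exc
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(rotation=self.rotation.T,
                              translation=-self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous form."""
        h = np.eye(4)
        h[:3, :3] = self.rotation
        h[:3, 3] = self.translation
        return h


def _require_noncollinear(pts: np.ndarray) -> None:
    if len(pts) < 3:
        raise InsufficientMarkersError("need >= 3 markers")
    s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("markers are collinear")


def pose_from_markers(template: MarkerTemplate, frame: MarkerFrame):
    """Least-squares rigid transform mapping template -> frame positions.

    Closed-form Kabsch solution: centroid alignment followed by the SVD
    rotation, with the reflection case guarded by a determinant sign flip.
    Only markers visible in the frame participate.

    Returns ``(RigidTransform, rmsd_mm)``.
    """
    vis = frame.visibility
    if int(np.sum(vis)) < 3:
        raise InsufficientMarkersError(
            f"only {int(np.sum(vis))} visible markers (need >= 3)")
    p = template.reference_positions[vis]
    q = frame.positions[vis]
    _require_noncollinear(p)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = qc - r @ pc
    tf = RigidTransform(rotation=r, translation=t)
    rmsd = float(np.sqrt(np.mean(np.sum((tf.apply(p) - q) ** 2, axis=1))))
    return tf, rmsd


def compose_chain(
    world_to_markers: RigidTransform,
    markers_to_plate: RigidTransform,
    plate_to_bone_acs: RigidTransform,
) -> RigidTransform:
    """Compose the calibration chain into a single world->bone-ACS transform.

    Applying the result to a point is equivalent to applying the three
    transforms in the stated order (markers, then acrylic plate, then bone
    ACS); equal to the product of the 4x4 homogeneous matrices
    ``plate_to_bone_acs @ markers_to_plate @ world_to_markers``.
    """
    for tf in (world_to_markers, markers_to_plate, plate_to_bone_acs):
        if not isinstance(tf, RigidTransform):
            raise InvalidTransformError("compose_chain expects RigidTransforms")
    r = plate_to_bone_acs.rotation @ markers_to_plate.rotation @ world_to_markers.rotation
    t = plate_to_bone_acs.apply(markers_to_plate.apply(world_to_markers.translation))
    return RigidTransform(rotation=r, translation=t)


def track_markers(template: MarkerTemplate, frames: list, rate_hz: float = 30.0,
                  meta: dict | None = None):
    """Solve every frame; frames with < 3 visible markers are dropped.

    Returns ``(PoseSequence, rmsd_per_frame, dropped_indices)``.
    """
    rots, times, rmsds, dropped = [], [], [], []
    for i, fr in enumerate(frames):
        try:
            tf, rmsd = pose_from_markers(template, fr)
        except InsufficientMarkersError:
            dropped.append(i)
            continue
        rots.append(tf.rotation)
        times.append(fr.time)
        rmsds.append(rmsd)
    if not rots:
        raise InsufficientMarkersError("no solvable frames in trial")
    seq = PoseSequence(frames=np.stack(rots), times=np.asarray(times),
                       rate_hz=rate_hz, meta=dict(meta or {}))
    return seq, np.asarray(rmsds), dropped


def detect_pose_jumps(seq: PoseSequence, max_step_deg: float = DEFAULT_JUMP_DEG):
    """Flag frames that jump discontinuously out of the previous pose space.

    A sudden increase in rotational range without gradual continuity
    indicates joint damage; frame ``i`` is flagged when the geodesic angle
    from frame ``i-1`` exceeds ``max_step_deg``.  Returns
    ``(indices, step_magnitudes_deg)``.
    """
    idx, mags = [], []
    for i in range(1, len(seq)):
        step = geodesic_angle(seq.frames[i - 1], seq.frames[i])
        if step > max_step_deg:
            idx.append(i)
            mags.append(step)
    return idx, mags


def filter_sufficient_trials(trials: list, max_step_deg: float = DEFAULT_JUMP_DEG):
    """Apply the discard and sufficiency rules to one specimen's trials.

    Each trial's ``meta['sweep']`` must be a planar label
    (``planar-FE/-ABAD/-LAR``) or one of the six interaction sequences
    (FAL, FLA, AFL, ALF, LFA, LAF).  Trials with pose jumps are rejected.
    The specimen is sufficient iff all three planar labels survive and at
    least two interaction trials survive.

    Returns ``(kept, rejected, sufficient)``.
    """
    kept, rejected = [], []
    for trial in trials:
        label = trial.meta.get("sweep")
        if label not in PLANAR_LABELS and label not in INTERACTION_LABELS:
            raise MissingLabelError(f"trial has unknown sweep label {label!r}")
        jumps, _ = detect_pose_jumps(trial, max_step_deg)
        (rejected if jumps else kept).append(trial)
    planar = {t.meta["sweep"] for t in kept if t.meta["sweep"] in PLANAR_LABELS}
    n_interaction = sum(1 for t in kept if t.meta["sweep"] in INTERACTION_LABELS)
    sufficient = planar == set(PLANAR_LABELS) and n_interaction >= 2
    return kept, rejected, sufficient
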