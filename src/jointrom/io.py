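"""Readers and writers for the pipeline's plain-text formats.

Pose tables are CSV with either a rotation-matrix header
(``frame,time_s,r11..r33``) or an Euler header
(``frame,time_s,fe_z,abad_y,lar_x``), auto-detected; metadata travels in
leading ``# key=value`` comment lines or a ``<path>.meta.json`` sidecar.
Angles are always serialised in degrees.  Readers reject malformed input
rather than coercing it; writers are deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acs import ACS, LandmarkSet
from .errors import EmptyInputError, FormatError, InvalidRotationError, ValidationError
from .kinematics import (
    PoseSequence,
    check_rotation,
    euler_to_matrix_batch,
)
from .markers import MarkerFrame, MarkerTemplate, RigidTransform
from .sfp import AXES, RoMSummary, SFPTrace

log = logging.getLogger("jointrom")

MATRIX_COLS = ["frame", "time_s", "r11", "r12", "r13", "r21", "r22", "r23",
               "r31", "r32", "r33"]
EULER_COLS = ["frame", "time_s", "fe_z", "abad_y", "lar_x"]
ROM_TABLE_COLS = ["specimen", "context", "axis", "max", "min", "range",
                  "conc1_at_max", "conc2_at_max", "conc1_at_min", "conc2_at_min"]


@dataclass
class RunConfig:
    """Pipeline run configuration loaded from YAML or JSON."""

    paths: dict = field(default_factory=dict)
    joint: str = "hip"
    side: str = "right"
    region_method: str = "convex_hull"
    alpha_deg: float = 15.0
    jump_threshold_deg: float = 15.0
    round_tables: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.joint not in ("hip", "knee"):
            raise ValidationError(f"unknown joint {self.joint!r}")
        if self.side not in ("left", "right"):
            raise ValidationError(f"unknown side {self.side!r}")
        if self.region_method not in ("convex_hull", "alpha_shape"):
            raise ValidationError(f"unknown region method {self.region_method!r}")
        for key, p in self.paths.items():
            if not Path(p).exists():
                raise ValidationError(f"config path {key!r} does not exist: {p}")


def load_run_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML (or JSON) file."""
    obj = yaml.safe_load(Path(path).read_text())
    if not isinstance(obj, dict):
        raise FormatError(f"{path}: expected a mapping at top level")
    try:
        return RunConfig(**obj)
    except TypeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _read_meta(path: Path) -> dict:
    meta = {}
    sidecar = Path(str(path) + ".meta.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def read_pose_table(path) -> PoseSequence:
    """Read a pose-sequence CSV (matrix or Euler form, auto-detected)."""
    path = Path(path)
    meta = _read_meta(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    cols = list(df.columns)
    if cols == MATRIX_COLS:
        vals = df[MATRIX_COLS[2:]].to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or not np.all(np.isfinite(vals)):
            raise ValidationError(f"{path}: non-numeric matrix entries")
        frames = vals.reshape(-1, 3, 3)
        for i, f in enumerate(frames):
            try:
                check_rotation(f, atol=1e-6)
            except InvalidRotationError as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from exc
    elif cols == EULER_COLS:
        ang = df[EULER_COLS[2:]].to_numpy()
        if not np.issubdtype(ang.dtype, np.number) or not np.all(np.isfinite(ang)):
            raise ValidationError(f"{path}: non-finite Euler angles")
        frames = euler_to_matrix_batch(ang)
    else:
        raise FormatError(
            f"{path}: unknown header {cols!r}; expected matrix or Euler form")
    times = df["time_s"].to_numpy(dtype=float)
    rate = float(meta.pop("rate_hz", 30.0))
    return PoseSequence(frames=frames, times=times, rate_hz=rate, meta=meta)


def write_pose_table(seq: PoseSequence, path, form: str = "matrix") -> None:
    """Write a pose sequence as CSV with ``# key=value`` metadata lines."""
    path = Path(path)
    lines = [f"# {k}={v}" for k, v in sorted(seq.meta.items())
             if isinstance(v, (str, int, float, bool))]
    if form == "matrix":
        data = seq.frames.reshape(len(seq), 9)
        df = pd.DataFrame(data, columns=MATRIX_COLS[2:])
    elif form == "euler":
        df = pd.DataFrame(seq.to_euler(), columns=EULER_COLS[2:])
    else:
        raise ValidationError(f"unknown pose-table form {form!r}")
    df.insert(0, "time_s", seq.times)
    df.insert(0, "frame", np.arange(len(seq)))
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_landmarks(path) -> LandmarkSet:
    """Read landmarks from CSV ``name,region,x,y,z`` or a JSON mapping."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        return LandmarkSet(
            proximal_perimeter=np.asarray(obj["proximal_perimeter"], dtype=float),
            distal_perimeter=np.asarray(obj["distal_perimeter"], dtype=float),
            reference_points={k: np.asarray(v, dtype=float)
                              for k, v in obj.get("reference_points", {}).items()},
            bone=obj.get("bone", ""), side=obj.get("side", "right"))
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != ["name", "region", "x", "y", "z"]:
        raise FormatError(f"{path}: expected header name,region,x,y,z")
    xyz = df[["x", "y", "z"]].to_numpy()
    if not np.issubdtype(xyz.dtype, np.number) or not np.all(np.isfinite(xyz)):
        raise ValidationError(f"{path}: non-numeric landmark coordinates")
    groups = {"proximal_perimeter": [], "distal_perimeter": []}
    refs = {}
    for i, row in df.iterrows():
        region = row["region"]
        if region in groups:
            groups[region].append(xyz[i])
        elif region == "reference":
            refs[str(row["name"])] = xyz[i]
        else:
            raise ValidationError(f"{path}: unknown region {region!r} (row {i})")
    return LandmarkSet(proximal_perimeter=np.asarray(groups["proximal_perimeter"]),
                       distal_perimeter=np.asarray(groups["distal_perimeter"]),
                       reference_points=refs)


def write_acs_json(acs: ACS, path) -> None:
    obj = {"origin": list(acs.origin), "x_axis": list(acs.x_axis),
           "y_axis": list(acs.y_axis), "z_axis": list(acs.z_axis),
           "bone": acs.bone, "side": acs.side,
           "residuals": {k: (float(v) if not isinstance(v, bool) else v)
                         for k, v in acs.residuals.items()}}
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_transform_json(path) -> RigidTransform:
    """Read a rigid transform stored as {rotation: 3x3, translation: 3}."""
    obj = json.loads(Path(path).read_text())
    return RigidTransform(rotation=np.asarray(obj["rotation"], dtype=float),
                          translation=np.asarray(obj["translation"], dtype=float))


def read_marker_template(path) -> MarkerTemplate:
    obj = json.loads(Path(path).read_text())
    return MarkerTemplate(marker_ids=list(obj["marker_ids"]),
                          reference_positions=np.asarray(obj["reference_positions"],
                                                         dtype=float))


def read_marker_frames(path) -> list:
    """Read marker frames from CSV ``time_s,<id>_x,<id>_y,<id>_z,...``."""
    df = pd.read_csv(path, comment="#")
    if df.columns[0] != "time_s" or (len(df.columns) - 1) % 3:
        raise FormatError(f"{path}: expected time_s plus xyz triples")
    n_markers = (len(df.columns) - 1) // 3
    frames = []
    for _, row in df.iterrows():
        pos = row.iloc[1:].to_numpy(dtype=float).reshape(n_markers, 3)
        frames.append(MarkerFrame(time=float(row["time_s"]), positions=pos))
    return frames


def write_rom_table(summaries, path) -> None:
    """Write RoM summaries as the standard whole-degree table CSV.

    One row per specimen x axis; every cell integer-rounded (range rounded
    from the unrounded range).  Re-reading reproduces the rounded values
    exactly.
    """
    if not summaries:
        raise EmptyInputError("no summaries to write")
    rows = []
    for s in summaries:
        table = s.rounded_table()
        for axis in AXES:
            cell = table[axis]
            conc = [a for a in range(3) if a != {"FE": 0, "ABAD": 1, "LAR": 2}[axis]]
            rows.append({
                "specimen": s.meta.get("specimen", ""),
                "context": s.meta.get("context", ""),
                "axis": axis,
                "max": cell["max"], "min": cell["min"], "range": cell["range"],
                "conc1_at_max": cell["at_max"][conc[0]],
                "conc2_at_max": cell["at_max"][conc[1]],
                "conc1_at_min": cell["at_min"][conc[0]],
                "conc2_at_min": cell["at_min"][conc[1]],
            })
    df = pd.DataFrame(rows, columns=ROM_TABLE_COLS)
    df.to_csv(path, index=False, lineterminator="\n")


def read_rom_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != ROM_TABLE_COLS:
        raise FormatError(f"{path}: not a RoM table")
    return df


def write_sfp_json(trace: SFPTrace, path, regions: dict | None = None) -> None:
    """Export SFP tips (and optional region boundaries) as JSON."""
    obj = {"x_tips": trace.x_tips.tolist(), "y_tips": trace.y_tips.tolist(),
           "z_tips": trace.z_tips.tolist(),
           "meta": {k: v for k, v in trace.meta.items()
                    if isinstance(v, (str, int, float, bool, list, dict))}}
    if regions:
        obj["regions"] = {axis: {"boundary": reg.boundary.tolist(),
                                 "centroid": reg.centroid.tolist(),
                                 "max_angular_radius": reg.max_angular_radius,
                                 "method": reg.method}
                          for axis, reg in regions.items()}
    Path(path).write_text(json.dumps(obj) + "\n")
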