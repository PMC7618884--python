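"""3D skeleton sequences, joint conventions, and turn annotations.

The in-memory model is a ``SkeletonSequence``: a ``T x J x 3`` coordinate
tensor with a frame rate, an ordered joint-name list and an optional
validity mask. The default convention is the 17-joint Human3.6M skeleton.
Coordinates are unit-agnostic: every downstream quantity is an angle or an
angular rate, both invariant to uniform scaling.

File formats are deliberately plain text:

* skeleton CSV — long form, columns ``frame,joint,x,y,z`` (0-based frames,
  header mandatory, UTF-8); masked joints carry empty coordinate fields.
* JSON manifest sidecar — keys ``fps``, ``convention``, ``up_axis``,
  ``source``.
* annotation CSV — columns
  ``clip_id,label_deg,start_s,end_s,subject_id,group,scenario,location``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_JOINTS",
    "H36M_JOINT_NAMES",
    "H36M_CONVENTION",
    "JointConvention",
    "SkeletonSequence",
    "TurnAnnotation",
    "SchemaError",
    "read_skeleton",
    "write_skeleton",
    "read_annotations",
    "write_annotations",
    "remap_convention",
]

#: Paired joints every convention must locate: they define the frontal plane.
CANONICAL_JOINTS = (
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_shoulder",
    "right_shoulder",
)

#: 17-joint Human3.6M ordering as commonly exported by 2D->3D lifting models.
H36M_JOINT_NAMES = (
    "pelvis",
    "right_hip",
    "right_knee",
    "right_ankle",
    "left_hip",
    "left_knee",
    "left_ankle",
    "spine",
    "thorax",
    "neck",
    "head",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
)

VALID_GROUPS = ("PD", "control")
VALID_SCENARIOS = ("scripted", "clinical", "free_living", "other")
DEFAULT_LABEL_SET = (45, 90, 135, 180, 225, 270, 315, 360)


class SchemaError(ValueError):
    """A file violates the documented schema (missing joints, bad header...)."""


@dataclass(frozen=True)
class JointConvention:
    """Mapping from canonical joint labels to column indices of a skeleton.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"h36m17"``.
    index_map : mapping
        Canonical label -> joint-axis index. Must be injective and cover the
        six canonical paired joints.
    """

    name: str
    index_map: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = [j for j in CANONICAL_JOINTS if j not in self.index_map]
        if missing:
            raise SchemaError(
                f"convention {self.name!r} lacks canonical joints: {missing}"
            )
        indices = list(self.index_map.values())
        if len(set(indices)) != len(indices):
            raise SchemaError(f"convention {self.name!r} index_map is not injective")

    def index(self, joint: str) -> int:
        return self.index_map[joint]


H36M_CONVENTION = JointConvention(
    name="h36m17",
    index_map={name: i for i, name in enumerate(H36M_JOINT_NAMES)},
)


@dataclass
class SkeletonSequence:
    """A time series of 3D joint coordinates.

    Attributes
    ----------
    coords : ndarray, shape (T, J, 3)
        Joint coordinates; units arbitrary but uniform. Masked entries may
        hold NaN.
    fps : float
        Frames per second, > 0.
    joint_names : tuple of str
        Ordered joint labels, length J.
    up_axis : {"x", "y", "z"}
        Which coordinate axis is vertical; the other two span the ground
        plane. Default ``"z"``.
    valid_mask : ndarray of bool, shape (T, J), optional
        True where the joint is observed. ``None`` means all valid.
    """

    coords: np.ndarray
    fps: float
    joint_names: Sequence[str] = H36M_JOINT_NAMES
    up_axis: str = "z"
    valid_mask: np.ndarray | None = None
    convention: JointConvention = field(default=H36M_CONVENTION)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (T, J, 3); got {self.coords.shape}")
        if self.coords.shape[1] != len(self.joint_names):
            raise ValueError(
                f"coords has {self.coords.shape[1]} joints but "
                f"{len(self.joint_names)} joint names"
            )
        if not np.isfinite(self.fps) or self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.up_axis not in ("x", "y", "z"):
            raise ValueError(f"up_axis must be one of x/y/z, got {self.up_axis!r}")
        for joint in CANONICAL_JOINTS:
            if list(self.joint_names).count(joint) != 1:
                raise SchemaError(
                    f"joint_names must contain exactly one {joint!r}"
                )
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.coords.shape[:2]:
                raise ValueError(
                    f"valid_mask shape {self.valid_mask.shape} does not match "
                    f"coords {self.coords.shape[:2]}"
                )
        # Unmasked coordinates must be finite; non-finite values must be masked.
        finite = np.isfinite(self.coords).all(axis=2)
        if self.valid_mask is None:
            if not finite.all():
                raise ValueError(
                    "non-finite coordinates present without a valid_mask"
                )
        elif not finite[self.valid_mask].all():
            raise ValueError("valid_mask marks non-finite coordinates as valid")

    # -- convenience -----------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_joints(self) -> int:
        return self.coords.shape[1]

    @property
    def duration_s(self) -> float:
        """Clip duration d = T / fps."""
        return self.n_frames / self.fps

    def joint_index(self, joint: str) -> int:
        return list(self.joint_names).index(joint)

    def mask(self) -> np.ndarray:
        """Validity mask, materialised (all-True if none stored)."""
        if self.valid_mask is None:
            return np.ones(self.coords.shape[:2], dtype=bool)
        return self.valid_mask

    def slice_frames(self, start: int, stop: int) -> "SkeletonSequence":
        """Sub-sequence over the half-open frame interval [start, stop)."""
        if not (0 <= start < stop <= self.n_frames):
            raise IndexError(
                f"frame slice [{start}, {stop}) out of range for T={self.n_frames}"
            )
        mask = None if self.valid_mask is None else self.valid_mask[start:stop]
        return replace(self, coords=self.coords[start:stop].copy(), valid_mask=mask)


@dataclass(frozen=True)
class TurnAnnotation:
    """A clinician-style turn label with cohort metadata."""

    clip_id: str
    label_deg: int
    start_s: float
    end_s: float
    subject_id: str
    group: str
    scenario: str = "other"
    location: str = ""

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(
                f"{self.clip_id}: end_s ({self.end_s}) must exceed start_s "
                f"({self.start_s})"
            )
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"{self.clip_id}: group must be one of {VALID_GROUPS}, "
                f"got {self.group!r}"
            )
        if self.scenario not in VALID_SCENARIOS:
            raise ValueError(
                f"{self.clip_id}: scenario must be one of {VALID_SCENARIOS}, "
                f"got {self.scenario!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SKELETON_COLUMNS = ["frame", "joint", "x", "y", "z"]
_ANNOTATION_COLUMNS = [
    "clip_id",
    "label_deg",
    "start_s",
    "end_s",
    "subject_id",
    "group",
    "scenario",
    "location",
]


def read_skeleton(
    path: str | Path,
    convention: JointConvention = H36M_CONVENTION,
    fps: float | None = None,
    up_axis: str | None = None,
) -> SkeletonSequence:
    """Read a long-form skeleton CSV (``frame,joint,x,y,z``).

    A JSON manifest sidecar (same stem, ``.json``) supplies ``fps`` and
    ``up_axis`` when the arguments are omitted. Rows with non-finite or
    empty coordinates become masked entries, never silent zeros. ``y``-up
    files are normalised to ``z``-up at load time (y and z axes swapped).
    """
    path = Path(path)
    manifest = _read_manifest(path)
    if fps is None:
        fps = manifest.get("fps")
    if fps is None:
        raise SchemaError(f"{path}: fps not given and no manifest provides it")
    if up_axis is None:
        up_axis = manifest.get("up_axis", "z")

    df = pd.read_csv(path)
    if list(df.columns) != _SKELETON_COLUMNS:
        raise SchemaError(
            f"{path}: expected header {_SKELETON_COLUMNS}, got {list(df.columns)}"
        )
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")

    frames = np.sort(df["frame"].unique())
    if not np.array_equal(frames, np.arange(len(frames))):
        raise SchemaError(
            f"{path}: frame indices must be contiguous 0-based integers"
        )
    # frames must be non-decreasing as written
    if (df["frame"].diff().dropna() < 0).any():
        raise SchemaError(f"{path}: non-monotone frame indices")

    joints_present = list(dict.fromkeys(df["joint"]))
    missing = [j for j in CANONICAL_JOINTS if j not in joints_present]
    if missing:
        raise SchemaError(f"{path}: missing canonical joint(s): {missing}")

    T = len(frames)
    J = len(joints_present)
    coords = np.full((T, J, 3), np.nan)
    jidx = {name: i for i, name in enumerate(joints_present)}
    rows_f = df["frame"].to_numpy(dtype=int)
    rows_j = df["joint"].map(jidx).to_numpy(dtype=int)
    coords[rows_f, rows_j, 0] = pd.to_numeric(df["x"], errors="coerce")
    coords[rows_f, rows_j, 1] = pd.to_numeric(df["y"], errors="coerce")
    coords[rows_f, rows_j, 2] = pd.to_numeric(df["z"], errors="coerce")

    valid = np.isfinite(coords).all(axis=2)
    coords[~valid] = np.nan

    if up_axis == "y":  # mocap-style export: swap to internal z-up
        coords = coords[:, :, [0, 2, 1]].copy()
        up_axis = "z"

    conv = convention
    if set(joints_present) != set(conv.index_map) or any(
        jidx[k] != v for k, v in conv.index_map.items() if k in jidx
    ):
        # File defines its own joint ordering; build a convention from it.
        conv = JointConvention(name=f"{path.stem}", index_map=jidx)

    return SkeletonSequence(
        coords=coords,
        fps=float(fps),
        joint_names=tuple(joints_present),
        up_axis=up_axis,
        valid_mask=None if valid.all() else valid,
        convention=conv,
    )


def _read_manifest(csv_path: Path) -> dict:
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}


def write_skeleton(
    seq: SkeletonSequence, path: str | Path, manifest: bool = True
) -> None:
    """Write the long-form CSV (and a JSON manifest sidecar by default).

    Masked joints are written with empty coordinate fields, preserving the
    mask across a round-trip. Coordinates are serialised with full float
    precision (repr), so read-after-write reproduces them within 1e-9
    relative tolerance.
    """
    path = Path(path)
    T, J, _ = seq.coords.shape
    mask = seq.mask()
    frames = np.repeat(np.arange(T), J)
    joints = np.tile(np.asarray(seq.joint_names, dtype=object), T)
    flat = seq.coords.reshape(T * J, 3)
    flat_mask = mask.reshape(T * J)
    cols = {}
    for k, axis in enumerate("xyz"):
        vals = np.array([repr(float(v)) for v in flat[:, k]], dtype=object)
        vals[~flat_mask] = ""
        cols[axis] = vals
    df = pd.DataFrame(
        {"frame": frames, "joint": joints, "x": cols["x"], "y": cols["y"], "z": cols["z"]}
    )
    df.to_csv(path, index=False)
    if manifest:
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(
                {
                    "fps": seq.fps,
                    "convention": seq.convention.name,
                    "up_axis": seq.up_axis,
                    "source": "turnmetry",
                },
                fh,
                indent=2,
            )


def read_annotations(
    path: str | Path, label_set: Sequence[int] = DEFAULT_LABEL_SET
) -> list[TurnAnnotation]:
    """Read and validate a turn-annotation CSV.

    Labels outside ``label_set`` are rejected outright — a 100° label is a
    data error, not something to quantise silently.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"clip_id": str, "subject_id": str})
    if list(df.columns) != _ANNOTATION_COLUMNS:
        raise SchemaError(
            f"{path}: expected header {_ANNOTATION_COLUMNS}, got {list(df.columns)}"
        )
    out = []
    allowed = set(int(b) for b in label_set)
    for row in df.itertuples(index=False):
        label = int(row.label_deg)
        if label not in allowed:
            raise ValueError(
                f"{path}: label_deg {label} not in the configured label set "
                f"{sorted(allowed)}"
            )
        out.append(
            TurnAnnotation(
                clip_id=str(row.clip_id),
                label_deg=label,
                start_s=float(row.start_s),
                end_s=float(row.end_s),
                subject_id=str(row.subject_id),
                group=str(row.group),
                scenario=str(row.scenario),
                location="" if pd.isna(row.location) else str(row.location),
            )
        )
    return out


def write_annotations(annotations: Sequence[TurnAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "clip_id": a.clip_id,
                "label_deg": a.label_deg,
                "start_s": a.start_s,
                "end_s": a.end_s,
                "subject_id": a.subject_id,
                "group": a.group,
                "scenario": a.scenario,
                "location": a.location,
            }
            for a in annotations
        ],
        columns=_ANNOTATION_COLUMNS,
    ).to_csv(path, index=False)


def remap_convention(
    seq: SkeletonSequence, target: JointConvention, target_names: Sequence[str]
) -> SkeletonSequence:
    """Permute the joint axis into another convention's ordering.

    ``target_names`` gives the full joint ordering of the target layout;
    every joint of ``seq`` must appear in it. The operation is a pure
    permutation, so remapping there and back is bit-identical.
    """
    src_names = list(seq.joint_names)
    if sorted(src_names) != sorted(target_names):
        raise SchemaError("target convention does not cover the same joint set")
    perm = [src_names.index(name) for name in target_names]
    mask = None if seq.valid_mask is None else seq.valid_mask[:, perm]
    return replace(
        seq,
        coords=seq.coords[:, perm],
        joint_names=tuple(target_names),
        valid_mask=mask,
        convention=target,
    )
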