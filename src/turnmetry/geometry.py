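"""Turning-angle kinematics from ground-plane joint-pair vectors.

The facing direction of a body is read from left-minus-right joint-pair
vectors (hips, knees, shoulders) projected onto the horizontal plane. For
consecutive frames t, t+1 the per-frame turning increment is

    theta_t = arcsin( ||v_t x v_{t+1}|| / (||v_t|| ||v_{t+1}||) )

averaged with equal weights across the selected joint pairs. The cumulative
turning angle is theta = sum_t theta_t, the angular speed omega = theta / d
for a clip of duration d, and the maximum angular velocity

    w_max = max_t theta_t / dt,      dt = 1 / fps.

Notes on the two increment modes:

* ``faithful`` (default) uses the arcsin-of-cross-norm form above. It is
  unsigned and aliases per-step angles above 90 deg (arcsin returns the
  supplement); this is the method's published behaviour and is kept as-is.
* ``signed`` uses atan2(cross, dot), giving a signed increment in
  (-180, 180]. It is the right tool for direction-aware work such as turn
  segmentation, and is robust to gait oscillation, which cancels instead of
  accumulating.

A dimensional remark on w_max: multiplying the maximum per-frame increment
by dt (seconds per frame) would yield degree-seconds; dividing by dt gives
the degrees-per-second rate that the quantity denotes and that group
statistics report. This module divides.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .skeleton import SkeletonSequence

__all__ = [
    "GroundPlaneVector",
    "TurnEstimate",
    "DegenerateFrameError",
    "InsufficientFramesError",
    "JOINT_PAIRS",
    "pair_vector",
    "pair_vectors",
    "frame_increment",
    "cumulative_angle",
    "angular_speed",
    "max_angular_velocity",
    "quantize_to_bin",
]

logger = logging.getLogger(__name__)

#: joint-pair label -> (left joint, right joint)
JOINT_PAIRS = {
    "hip": ("left_hip", "right_hip"),
    "knee": ("left_knee", "right_knee"),
    "shoulder": ("left_shoulder", "right_shoulder"),
}

#: Relative norm threshold below which a pair vector counts as degenerate.
ZERO_NORM_RTOL = 1e-9

_GROUND_AXES = {"z": (0, 1), "y": (0, 2), "x": (1, 2)}


class DegenerateFrameError(ValueError):
    """A frame's pair vector is unusable (masked or zero-norm) with no fallback."""


class InsufficientFramesError(ValueError):
    """The sequence has too few frames for the requested computation."""


@dataclass(frozen=True)
class GroundPlaneVector:
    """A left-minus-right joint-pair vector projected onto the ground plane."""

    vx: float
    vy: float
    valid: bool = True

    @property
    def norm(self) -> float:
        return float(np.hypot(self.vx, self.vy))

    def as_array(self) -> np.ndarray:
        return np.array([self.vx, self.vy])


@dataclass
class TurnEstimate:
    """Kinematic summary of one turning clip.

    Attributes
    ----------
    theta_deg : float
        Cumulative turning angle (deg); the sum of ``increments_deg``.
    increments_deg : ndarray, shape (T-1,)
        Per-frame-pair increments theta_t.
    omega_deg_s : float
        Angular speed theta / d (deg/s).
    wmax_deg_s : float
        Maximum angular velocity: max |theta_t| * fps (deg/s).
    duration_s : float
        Clip duration d (s).
    joint_sets : tuple of str
        Which joint pairs were averaged.
    mode : str
        ``"faithful"`` or ``"signed"``.
    n_skipped_frames : int
        Frames whose pair vectors were degenerate and replaced by the last
        valid vector.
    """

    theta_deg: float
    increments_deg: np.ndarray
    omega_deg_s: float
    wmax_deg_s: float
    duration_s: float
    joint_sets: tuple[str, ...]
    mode: str = "faithful"
    n_skipped_frames: int = 0

    def __post_init__(self) -> None:
        self.increments_deg = np.asarray(self.increments_deg, dtype=float)
        if not np.isclose(self.theta_deg, self.increments_deg.sum(), atol=1e-9):
            raise ValueError("theta_deg must equal the sum of increments_deg")


# ---------------------------------------------------------------------------
# pair vectors
# ---------------------------------------------------------------------------


def _ground_axes(seq: SkeletonSequence) -> tuple[int, int]:
    return _GROUND_AXES[seq.up_axis]


def pair_vectors(seq: SkeletonSequence, pair: str) -> tuple[np.ndarray, np.ndarray]:
    """All frames' ground-plane vectors for one joint pair.

    Returns ``(vecs, valid)`` where ``vecs`` has shape (T, 2) and ``valid``
    flags frames whose both joints are observed and whose vector norm
    exceeds the degeneracy threshold (1e-9 of the median pair norm).
    """
    if pair not in JOINT_PAIRS:
        raise KeyError(f"unknown joint pair {pair!r}; choose from {list(JOINT_PAIRS)}")
    left_name, right_name = JOINT_PAIRS[pair]
    li = seq.joint_index(left_name)
    ri = seq.joint_index(right_name)
    ax, ay = _ground_axes(seq)
    left = seq.coords[:, li][:, [ax, ay]]
    right = seq.coords[:, ri][:, [ax, ay]]
    vecs = left - right
    mask = seq.mask()
    observed = mask[:, li] & mask[:, ri]
    norms = np.hypot(vecs[:, 0], vecs[:, 1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaNs from masked rows
        scale = np.nanmedian(np.where(observed, norms, np.nan))
    if not np.isfinite(scale) or scale == 0:
        scale = 1.0
    valid = observed & (norms > ZERO_NORM_RTOL * scale)
    vecs = np.where(valid[:, None], vecs, np.nan)
    return vecs, valid


def pair_vector(seq: SkeletonSequence, frame: int, pair: str) -> GroundPlaneVector:
    """Ground-plane pair vector at one frame (left joint minus right joint).

    A masked or zero-norm frame falls back to the most recent valid frame;
    with no earlier valid frame the frame is degenerate.
    """
    if not 0 <= frame < seq.n_frames:
        raise IndexError(f"frame {frame} out of range for T={seq.n_frames}")
    vecs, valid = pair_vectors(seq, pair)
    if valid[frame]:
        return GroundPlaneVector(float(vecs[frame, 0]), float(vecs[frame, 1]), True)
    earlier = np.nonzero(valid[: frame + 1])[0]
    if earlier.size == 0:
        raise DegenerateFrameError(
            f"frame {frame}: {pair} pair vector degenerate with no earlier "
            "valid frame"
        )
    j = int(earlier[-1])
    return GroundPlaneVector(float(vecs[j, 0]), float(vecs[j, 1]), False)


# ---------------------------------------------------------------------------
# increments and accumulation
# ---------------------------------------------------------------------------


def _increments_from_vecs(vecs: np.ndarray, mode: str) -> np.ndarray:
    """Per-frame-pair angles (deg) between consecutive rows of (T, 2)."""
    a = vecs[:-1]
    b = vecs[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
    norms = np.hypot(a[:, 0], a[:, 1]) * np.hypot(b[:, 0], b[:, 1])
    if mode == "faithful":
        ratio = np.clip(np.abs(cross) / norms, 0.0, 1.0)
        return np.degrees(np.arcsin(ratio))
    if mode == "signed":
        return np.degrees(np.arctan2(cross, dot))
    raise ValueError(f"mode must be 'faithful' or 'signed', got {mode!r}")


def frame_increment(
    v_t: GroundPlaneVector | np.ndarray,
    v_t1: GroundPlaneVector | np.ndarray,
    mode: str = "faithful",
) -> float:
    """Turning increment between two ground-plane vectors, in degrees.

    ``faithful`` returns arcsin(||v_t x v_{t+1}|| / (||v_t|| ||v_{t+1}||)),
    an unsigned value in [0, 90]; ``signed`` returns the atan2-based signed
    angle in (-180, 180].
    """
    a = v_t.as_array() if isinstance(v_t, GroundPlaneVector) else np.asarray(v_t, float)
    b = (
        v_t1.as_array()
        if isinstance(v_t1, GroundPlaneVector)
        else np.asarray(v_t1, float)
    )
    na, nb = np.hypot(*a), np.hypot(*b)
    if na == 0 or nb == 0 or not (np.isfinite(na) and np.isfinite(nb)):
        raise DegenerateFrameError("zero-norm or non-finite input vector")
    return float(_increments_from_vecs(np.stack([a, b]), mode)[0])


def _filled_vectors(seq: SkeletonSequence, pair: str) -> tuple[np.ndarray, int]:
    """Pair vectors with degenerate frames replaced by the nearest valid one.

    Interior gaps carry the last valid vector forward (their increments are
    zero); leading degenerate frames borrow the first valid vector. Returns
    the filled (T, 2) array and the number of replaced frames.
    """
    vecs, valid = pair_vectors(seq, pair)
    n_bad = int((~valid).sum())
    if n_bad == 0:
        return vecs, 0
    if not valid.any():
        raise DegenerateFrameError(
            f"{pair} pair vector is degenerate in every frame"
        )
    idx = np.arange(seq.n_frames)
    last_valid = np.where(valid, idx, -1)
    np.maximum.accumulate(last_valid, out=last_valid)
    first_valid = int(np.nonzero(valid)[0][0])
    last_valid[last_valid < 0] = first_valid
    logger.warning(
        "%s pair: %d/%d degenerate frame(s) carried forward", pair, n_bad, seq.n_frames
    )
    return vecs[last_valid], n_bad


def cumulative_angle(
    seq: SkeletonSequence,
    joint_sets: Sequence[str] = ("hip", "knee"),
    mode: str = "faithful",
) -> TurnEstimate:
    """Cumulative turning angle of a clip, averaged over joint pairs.

    Per frame pair, the increments of the selected joint-pair vectors are
    averaged with equal weights (the hip+knee default is the usual
    half-and-half combination; any subset of hip/knee/shoulder works the
    same way). theta is the sum of averaged increments over t = 0..T-2.
    """
    if seq.n_frames < 2:
        raise InsufficientFramesError(
            f"need at least 2 frames, got {seq.n_frames}"
        )
    joint_sets = tuple(joint_sets)
    if not joint_sets:
        raise ValueError("joint_sets must be non-empty")
    per_pair = []
    n_skipped = 0
    for pair in joint_sets:
        vecs, n_bad = _filled_vectors(seq, pair)
        n_skipped += n_bad
        per_pair.append(_increments_from_vecs(vecs, mode))
    increments = np.mean(per_pair, axis=0)
    theta = float(increments.sum())
    duration = seq.duration_s
    return TurnEstimate(
        theta_deg=theta,
        increments_deg=increments,
        omega_deg_s=angular_speed(theta, duration),
        wmax_deg_s=max_angular_velocity(increments, seq.fps),
        duration_s=duration,
        joint_sets=joint_sets,
        mode=mode,
        n_skipped_frames=n_skipped,
    )


def angular_speed(theta_deg: float, duration_s: float) -> float:
    """Average angular speed omega = theta / d, in deg/s."""
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    return theta_deg / duration_s


def max_angular_velocity(increments_deg: Sequence[float], fps: float) -> float:
    """Maximum angular velocity: largest per-frame increment as a rate.

    w_max = max_t |theta_t| / dt with dt = 1/fps, i.e. max(|theta_t|) * fps,
    in deg/s. (The per-frame increment divided — not multiplied — by the
    frame interval, so the result carries rate units.)
    """
    inc = np.asarray(increments_deg, dtype=float)
    if inc.size == 0:
        raise InsufficientFramesError("no increments: need at least 2 frames")
    if fps <= 0:
        raise ValueError(f"fps must be positive, got {fps}")
    return float(np.max(np.abs(inc)) * fps)


# ---------------------------------------------------------------------------
# quantisation
# ---------------------------------------------------------------------------


def quantize_to_bin(
    theta_deg: float,
    label_set: Sequence[int] = (45, 90, 135, 180, 225, 270, 315, 360),
    clamp: bool = True,
) -> int | None:
    """Quantise a turning angle to the nearest 45-degree bin label.

    Anything within +/-22.5 deg of a bin gets that bin's label (e.g. the
    whole range 90 +/- 22.5 maps to 90). Exact midpoints round half up to
    the larger bin. Angles beyond the largest bin clamp to it. Angles below
    the smallest bin's lower edge clamp to the smallest bin when ``clamp``
    is true, else return ``None`` (sub-threshold).
    """
    if theta_deg < 0:
        raise ValueError(f"theta_deg must be >= 0, got {theta_deg}")
    bins = np.sort(np.asarray(label_set, dtype=float))
    if bins.size == 0:
        raise ValueError("label_set must be non-empty")
    if not np.allclose(bins % 45, 0):
        raise ValueError("label_set entries must be multiples of 45 degrees")
    if not clamp and theta_deg < bins[0] - 22.5:
        return None
    dist = np.abs(bins - theta_deg)
    best = dist.min()
    # round half up: of the tied bins, take the larger
    candidates = bins[np.isclose(dist, best, rtol=0, atol=1e-12)]
    return int(candidates.max())
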