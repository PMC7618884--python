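"""Segmentation of turning episodes from continuous skeleton streams.

A turning episode runs from the initiation of pelvis rotation to the
completion of the movement. Detection works on the hip pair alone: the
unwrapped atan2 heading of the ground-plane hip vector gives a signed yaw
track whose derivative is the pelvis angular velocity. A hysteresis
threshold on that velocity opens a candidate segment (|yaw rate| >=
``omega_start``), keeps it open while the rate stays above ``omega_stop``
(tolerating up to ``max_gap_frames`` consecutive slow frames), and closes
it otherwise. Candidates whose net rotation magnitude falls below
``threshold_deg`` — 45 deg by default, the minimum rotation that counts as
a turn — are discarded.

The hysteresis parameters are tunables of this implementation, not part of
the published method (which curated turns manually); defaults are
omega_start = 25 deg/s, omega_stop = 10 deg/s, max_gap_frames = fps/4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    InsufficientFramesError,
    TurnEstimate,
    _filled_vectors,
    quantize_to_bin,
)
from .skeleton import SkeletonSequence

__all__ = ["TurnSegment", "detect_turns", "extract_clip", "bin_summary", "hip_yaw_track"]


@dataclass(frozen=True)
class TurnSegment:
    """A detected turning episode over the half-open frame interval [start, end)."""

    start_frame: int
    end_frame: int
    accumulated_deg: float
    direction: str  # "cw" | "ccw" | "mixed"

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame + 1:
            raise ValueError("segment must span at least 2 frames")
        if self.direction not in ("cw", "ccw", "mixed"):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def hip_yaw_track(seq: SkeletonSequence) -> np.ndarray:
    """Unwrapped signed heading (deg) of the hip pair vector, per frame.

    Degenerate frames inherit the nearest valid vector, so the track is
    defined everywhere and free of wrap-around jumps.
    """
    vecs, _ = _filled_vectors(seq, "hip")
    yaw = np.unwrap(np.arctan2(vecs[:, 1], vecs[:, 0]))
    return np.degrees(yaw)


def detect_turns(
    seq: SkeletonSequence,
    threshold_deg: float = 45.0,
    omega_start: float = 25.0,
    omega_stop: float = 10.0,
    max_gap_frames: int | None = None,
) -> list[TurnSegment]:
    """Find maximal non-overlapping turning episodes in a stream.

    Parameters
    ----------
    seq : SkeletonSequence
        Continuous stream, T >= 3 frames.
    threshold_deg : float
        Minimum net rotation magnitude for a candidate to count as a turn.
    omega_start, omega_stop : float
        Hysteresis opening / sustaining yaw-rate thresholds (deg/s);
        ``omega_stop <= omega_start``.
    max_gap_frames : int, optional
        Consecutive sub-``omega_stop`` frames tolerated inside a segment
        before it closes. Default: round(fps / 4).

    Returns
    -------
    list of TurnSegment, sorted by start frame.
    """
    if seq.n_frames < 3:
        raise InsufficientFramesError(f"need at least 3 frames, got {seq.n_frames}")
    if threshold_deg <= 0 or omega_start <= 0 or omega_stop <= 0:
        raise ValueError("thresholds must be positive")
    if omega_stop > omega_start:
        raise ValueError("omega_stop must not exceed omega_start")
    if max_gap_frames is None:
        max_gap_frames = int(round(seq.fps / 4))

    yaw = hip_yaw_track(seq)
    rate = np.abs(np.diff(yaw)) * seq.fps  # deg/s per frame pair t -> t+1

    segments: list[TurnSegment] = []
    t = 0
    n_pairs = rate.size
    while t < n_pairs:
        if rate[t] < omega_start:
            t += 1
            continue
        start = t
        gap = 0
        end_pair = t  # last fast frame pair seen
        while t < n_pairs:
            if rate[t] >= omega_stop:
                end_pair = t
                gap = 0
            else:
                gap += 1
                if gap > max_gap_frames:
                    break
            t += 1
        end = end_pair + 2  # include both frames of the last fast pair
        accumulated = yaw[end - 1] - yaw[start]
        if abs(accumulated) >= threshold_deg:
            segments.append(
                TurnSegment(
                    start_frame=start,
                    end_frame=end,
                    accumulated_deg=float(accumulated),
                    direction=_direction(yaw[start:end], accumulated),
                )
            )
        t = end
    return segments


def _direction(yaw_span: np.ndarray, accumulated: float) -> str:
    """ccw for net positive yaw, cw for negative; mixed if a reversal > 45 deg."""
    d = np.diff(yaw_span)
    pos_excursion = d[d > 0].sum()
    neg_excursion = -d[d < 0].sum()
    if min(pos_excursion, neg_excursion) > 45.0:
        return "mixed"
    return "ccw" if accumulated >= 0 else "cw"


def extract_clip(seq: SkeletonSequence, segment: TurnSegment) -> SkeletonSequence:
    """Trim the stream to a detected segment, preserving fps and masks."""
    if segment.end_frame > seq.n_frames:
        raise IndexError(
            f"segment [{segment.start_frame}, {segment.end_frame}) exceeds "
            f"T={seq.n_frames}"
        )
    return seq.slice_frames(segment.start_frame, segment.end_frame)


def bin_summary(estimates, label_set=(45, 90, 135, 180, 225, 270, 315, 360)):
    """Per-bin roll-up of turn estimates: counts, angle range, mean duration.

    Takes an iterable of :class:`~turnmetry.geometry.TurnEstimate` (or of
    ``(theta_deg, duration_s)`` pairs) and returns a DataFrame with one row
    per occupied bin plus a ``total`` row; means are weighted by count
    (i.e. computed over the pooled clips). Empty bins are omitted.
    """
    import pandas as pd

    rows = []
    for est in estimates:
        if isinstance(est, TurnEstimate):
            theta, dur = est.theta_deg, est.duration_s
        else:
            theta, dur = est
        rows.append((quantize_to_bin(abs(theta), label_set), abs(theta), dur))
    if not rows:
        raise ValueError("estimate list is empty")
    df = pd.DataFrame(rows, columns=["bin_deg", "theta_deg", "duration_s"])
    per_bin = (
        df.groupby("bin_deg")
        .agg(
            count=("theta_deg", "size"),
            min_deg=("theta_deg", "min"),
            max_deg=("theta_deg", "max"),
            mean_deg=("theta_deg", "mean"),
            mean_duration_s=("duration_s", "mean"),
        )
        .reset_index()
        .sort_values("bin_deg")
    )
    total = pd.DataFrame(
        [
            {
                "bin_deg": "total",
                "count": len(df),
                "min_deg": df["theta_deg"].min(),
                "max_deg": df["theta_deg"].max(),
                "mean_deg": df["theta_deg"].mean(),
                "mean_duration_s": df["duration_s"].mean(),
            }
        ]
    )
    return pd.concat([per_bin, total], ignore_index=True)
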