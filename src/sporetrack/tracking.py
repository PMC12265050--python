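"""Frame-to-frame linking of localizations into trajectories.

Linking is solved per consecutive frame pair as an optimal bipartite
assignment minimizing total squared displacement, with a hard distance
gate; unmatched localizations seed new tracks and a track ends after
``allow_gap_frames`` consecutive misses (default 0: PAmCherry bleaching
is irreversible on these timescales, so a missed frame terminates the
track).

The default gate of 0.4 um is about 3.9 standard deviations of the
per-axis step at D = 2.62e-2 um^2/s and dt = 0.1 s, accepting > 99.9%
of true Brownian steps at the largest diffusion coefficient of interest
while limiting identity swaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["Trajectory", "link_trajectories", "trajectory_filter",
           "trajectories_from_dataframe", "trajectories_to_dataframe"]

_BIG = 1e12


@dataclass
class Trajectory:
    """Time-ordered positions of one linked particle."""

    track_id: int
    frames: np.ndarray              # strictly increasing frame indices
    xy: np.ndarray                  # (n, 2) positions, um
    frame_interval: float = 0.1
    window_n_points: int | None = None   # set by trajectory_filter

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.frames.ndim != 1 or self.xy.shape != (self.frames.size, 2):
            raise ValueError("frames and xy shapes are inconsistent")
        if self.frames.size >= 2 and not (np.diff(self.frames) > 0).all():
            raise ValueError("frame indices must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.size

    @property
    def duration(self) -> float:
        """(n_frames - 1) * frame_interval, s."""
        return (self.n_frames - 1) * self.frame_interval

    @property
    def span_x(self) -> float:
        return float(np.ptp(self.xy[:, 0]))

    @property
    def span_y(self) -> float:
        return float(np.ptp(self.xy[:, 1]))


def link_trajectories(
    localizations: pd.DataFrame,
    max_link_distance: float = 0.4,
    allow_gap_frames: int = 0,
    frame_interval: float = 0.1,
) -> list[Trajectory]:
    """Link a (frame, x_um, y_um) table into trajectories.

    Per frame pair, candidate pairs within ``max_link_distance`` are
    matched by minimum total squared displacement (optimal assignment);
    ties resolve deterministically. Every localization belongs to
    exactly one output track; single-point tracks are returned too so
    the localization count is conserved.
    """
    if len(localizations) == 0:
        return []
    df = localizations.sort_values("frame", kind="stable")
    frames = df["frame"].to_numpy(dtype=int)
    pts = df[["x_um", "y_um"]].to_numpy(dtype=float)

    # active track state: id -> (last frame, last position)
    track_frames: dict[int, list[int]] = {}
    track_pts: dict[int, list[np.ndarray]] = {}
    active: list[int] = []
    next_id = 0
    gate2 = max_link_distance ** 2

    for f in np.unique(frames):
        idx = np.nonzero(frames == f)[0]
        cur = pts[idx]
        # drop tracks that have been dark for too long
        active = [t for t in active
                  if f - track_frames[t][-1] <= allow_gap_frames + 1]
        assigned = {}
        if active and len(cur):
            last = np.array([track_pts[t][-1] for t in active])
            d2 = ((last[:, None, :] - cur[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= gate2, d2, _BIG)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] < _BIG:
                    assigned[c] = active[r]
        new_active = []
        for k, i in enumerate(idx):
            if k in assigned:
                t = assigned[k]
            else:
                t = next_id
                next_id += 1
                track_frames[t] = []
                track_pts[t] = []
            track_frames[t].append(int(f))
            track_pts[t].append(pts[i])
            new_active.append(t)
        # tracks not extended this frame stay active until the gap runs out
        new_active.extend(t for t in active if t not in set(new_active))
        active = new_active

    return [Trajectory(track_id=t, frames=np.array(track_frames[t]),
                       xy=np.array(track_pts[t]), frame_interval=frame_interval)
            for t in sorted(track_frames)]


def trajectory_filter(
    trajectories: list[Trajectory],
    min_duration: float = 0.4,
    classification_window: float = 1.2,
) -> list[Trajectory]:
    """Keep tracks long enough to classify; set each classification window.

    A track is retained when its duration ``(n - 1) * dt`` is at least
    ``min_duration`` (0.4 s = 4 intervals, i.e. >= 5 points at 10 Hz).
    The mobility classification window is the first
    ``min(duration, classification_window)`` of the track, anchored at
    the track start; the number of points it covers is recorded on the
    trajectory (13 points for 1.2 s at 10 Hz).
    """
    out = []
    for t in trajectories:
        if t.duration + 1e-12 < min_duration:
            continue
        dt = t.frame_interval
        n_win = min(t.n_frames, int(np.floor(classification_window / dt + 1e-9)) + 1)
        t.window_n_points = n_win
        out.append(t)
    return out


def trajectories_to_dataframe(trajectories: list[Trajectory]) -> pd.DataFrame:
    rows = [(t.track_id, int(f), x, y)
            for t in trajectories for f, (x, y) in zip(t.frames, t.xy)]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])


def trajectories_from_dataframe(
    df: pd.DataFrame, frame_interval: float = 0.1
) -> list[Trajectory]:
    """Build trajectories from a (track_id, frame, x_um, y_um) table."""
    out = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        out.append(Trajectory(
            track_id=int(tid), frames=g["frame"].to_numpy(),
            xy=g[["x_um", "y_um"]].to_numpy(), frame_interval=frame_interval))
    return out
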