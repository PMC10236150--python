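"""Frame-to-frame linking, gap-tolerant track merging, and length filtering.

Linking follows the classic nearest-neighbour assignment contract of
particle-tracking packages: per frame, detections are assigned to open
tracks by minimizing total squared displacement subject to a maximum
per-cell displacement, with a short memory for temporarily lost cells.
Distances are Euclidean in micrometers in the drift-corrected frame; Z is
ignored (tracking happens after Z-collapse).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from slicetrack.detect import Detection

__all__ = ["Track", "link", "merge_tracks", "filter_min_length", "tracks_to_dataframe"]


@dataclass
class Track:
    """A time-ordered sequence of detections belonging to one cell."""

    track_id: int
    observations: list[Detection]
    merged_from: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError("a track needs at least one observation")
        frames = self.frames
        if np.any(np.diff(frames) <= 0):
            raise ValueError("observation frames must be strictly increasing")

    @property
    def frames(self) -> np.ndarray:
        return np.array([obs.frame for obs in self.observations])

    @property
    def start_frame(self) -> int:
        return self.observations[0].frame

    @property
    def end_frame(self) -> int:
        return self.observations[-1].frame

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    @property
    def start(self) -> Detection:
        return self.observations[0]

    @property
    def end(self) -> Detection:
        return self.observations[-1]

    def positions_um(self) -> np.ndarray:
        return np.array([[obs.x, obs.y] for obs in self.observations])


def link(detections: list[Detection], max_disp_um: float, memory: int = 1) -> list[Track]:
    """Link detections into tracks by per-frame optimal assignment.

    Assignment between open tracks and the detections of each frame
    minimizes total squared displacement; pairs farther apart than
    ``max_disp_um`` are never linked, and unassigned detections start new
    tracks.  A track missing from up to ``memory`` consecutive frames can
    still be extended (leaving a frame gap in its observations).
    """
    if max_disp_um <= 0:
        raise ValueError("max_disp_um must be > 0")
    if memory < 0:
        raise ValueError("memory must be >= 0")

    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame, []).append(det)

    tracks: list[Track] = []
    open_tracks: list[Track] = []
    next_id = 0
    big = 4 * max_disp_um**2 + 1.0

    for frame in sorted(by_frame):
        dets = sorted(by_frame[frame], key=lambda d: d.label)
        open_tracks = [t for t in open_tracks if frame - t.end_frame <= memory + 1]
        n_t, n_d = len(open_tracks), len(dets)
        assigned_det = [False] * n_d
        if n_t and n_d:
            # square cost matrix with virtual "no-link" rows/cols
            cost = np.full((n_t + n_d, n_d + n_t), 0.0)
            cost[:n_t, :n_d] = big
            for i, tr in enumerate(open_tracks):
                for j, det in enumerate(dets):
                    d2 = (tr.end.x - det.x) ** 2 + (tr.end.y - det.y) ** 2
                    if d2 <= max_disp_um**2:
                        cost[i, j] = d2
            cost[:n_t, n_d:] = big  # track goes unlinked this frame
            np.fill_diagonal(cost[:n_t, n_d:], max_disp_um**2 + 0.5)
            cost[n_t:, :n_d] = big  # detection starts a new track
            np.fill_diagonal(cost[n_t:, :n_d], max_disp_um**2 + 0.5)
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if i < n_t and j < n_d and cost[i, j] <= max_disp_um**2:
                    open_tracks[i].observations.append(dets[j])
                    assigned_det[j] = True
        for j, det in enumerate(dets):
            if not assigned_det[j]:
                track = Track(track_id=next_id, observations=[det])
                next_id += 1
                tracks.append(track)
                open_tracks.append(track)
    return tracks


def merge_tracks(
    tracks: list[Track],
    dist_thresh_um: float = 10.0,
    frame_gap_thresh: int = 2,
) -> list[Track]:
    """Merge broken track fragments.

    A pair (A ending at frame ``t_A``, B starting at ``t_B > t_A``) merges
    when ``t_B - t_A < frame_gap_thresh`` (strict: with the default of 2, a
    gap of 1 frame merges and a gap of 2 does not) and the distance between
    A's final and B's initial point is ``< dist_thresh_um`` (strict).  The
    spatially nearest candidate pair is merged first; merging repeats until
    no candidate remains.  ``merged_from`` records ancestry.  Tracks that
    overlap in time are never merged.
    """
    pool = [
        Track(
            track_id=t.track_id,
            observations=list(t.observations),
            merged_from=list(t.merged_from) or [t.track_id],
        )
        for t in tracks
    ]
    while True:
        best = None
        for i, a in enumerate(pool):
            for j, b in enumerate(pool):
                if i == j:
                    continue
                gap = b.start_frame - a.end_frame
                if gap <= 0 or gap >= frame_gap_thresh:
                    continue
                dist = a.end.distance_to(b.start)
                if dist >= dist_thresh_um:
                    continue
                key = (dist, gap, a.track_id, b.track_id)
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        a, b = pool[i], pool[j]
        merged = Track(
            track_id=min(a.track_id, b.track_id),
            observations=a.observations + b.observations,
            merged_from=sorted(set(a.merged_from) | set(b.merged_from)),
        )
        pool = [t for k, t in enumerate(pool) if k not in (i, j)] + [merged]
    return sorted(pool, key=lambda t: (t.start_frame, t.track_id))


def filter_min_length(tracks: list[Track], min_frames: int = 6) -> list[Track]:
    """Keep tracks observed in at least ``min_frames`` frames (counted after merging)."""
    return [t for t in tracks if t.n_observations >= min_frames]


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for obs in t.observations:
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": obs.frame,
                    "plane": obs.plane,
                    "x_um": obs.x,
                    "y_um": obs.y,
                    "area_um2": obs.area_um2,
                }
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "plane", "x_um", "y_um", "area_um2"])
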