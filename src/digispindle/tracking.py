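"""Frame-to-frame linking of comet detections into growth trajectories.

Linking is sequential: for every consecutive frame pair a globally optimal
one-to-one assignment is computed on the gated cost matrix of squared
displacements (linear assignment with a birth/death cost at the gate), so a
detection is linked only when no cheaper global arrangement exists.
Unmatched detections start or terminate tracks; tracks shorter than
``min_length`` points are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Track",
    "TrackingParams",
    "default_gate_um",
    "link_frame_pair",
    "build_tracks",
    "compute_mean_travel_speed",
    "tracks_to_frame",
    "track_summary",
]

_BIG = 1e12


@dataclass
class Track:
    """A linked trajectory: consecutive frames with one position each."""

    id: int
    start_frame: int
    positions_um: np.ndarray  # (n, 3) xyz
    mean_travel_speed: float = float("nan")
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)

    @property
    def n_points(self) -> int:
        return len(self.positions_um)

    @property
    def frames(self) -> np.ndarray:
        return self.start_frame + np.arange(self.n_points)

    @property
    def start_point_um(self) -> np.ndarray:
        return self.positions_um[0]

    @property
    def end_point_um(self) -> np.ndarray:
        return self.positions_um[-1]


@dataclass(frozen=True)
class TrackingParams:
    """Linking settings; ``gate_um=None`` uses :func:`default_gate_um`."""

    gate_um: float | None = None
    min_length: int = 4
    gap_closing: int = 0  # 0 or 1 frames; a closed gap is midpoint-interpolated
    speed_definition: str = "path"  # "path" or "net"
    interval_s: float = 0.755
    lateral_pitch_um: float = 0.104


def default_gate_um(interval_s: float, lateral_pitch_um: float,
                    max_speed_um_s: float = 1.0) -> float:
    """Gate radius: top-of-scale comet speed over one interval plus 2 pixels."""
    return max_speed_um_s * interval_s + 2.0 * lateral_pitch_um


def link_frame_pair(
    positions_t: np.ndarray, positions_t1: np.ndarray, gate_um: float
) -> list[tuple[int, int]]:
    """Optimal one-to-one links between two frames, within the gate.

    Returns index pairs ``(i, j)`` into the two position arrays.  The
    assignment minimises total squared displacement with a birth/death cost
    of ``gate_um**2`` per unmatched detection, so links beyond the gate never
    occur and links are dropped when starting/terminating is globally cheaper.
    """
    if gate_um <= 0:
        raise ValueError("gate_um must be positive")
    a = np.asarray(positions_t, dtype=float).reshape(-1, 3)
    b = np.asarray(positions_t1, dtype=float).reshape(-1, 3)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return []
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
    g2 = gate_um * gate_um
    cost = np.full((n + m, m + n), _BIG)
    cost[:n, :m] = np.where(d2 <= g2, d2, _BIG)
    cost[:n, m:] = np.where(np.eye(n, dtype=bool), g2, _BIG)  # deaths
    cost[n:, :m] = np.where(np.eye(m, dtype=bool), g2, _BIG)  # births
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and d2[i, j] <= g2
    ]


@dataclass(eq=False)
class _OpenTrack:
    frames: list[int] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)
    missed: int = 0


def build_tracks(
    detections: pd.DataFrame, params: TrackingParams = TrackingParams()
) -> list[Track]:
    """Link a detection table (frame, x_um, y_um, z_um) into tracks.

    Frames must be non-decreasing.  Optional one-frame gap closing keeps a
    track alive across a single missed frame and fills the hole with the
    midpoint of its neighbours.  Surviving tracks are id'd in frame-then-
    position order.
    """
    required = {"frame", "x_um", "y_um", "z_um"}
    if not required.issubset(detections.columns):
        raise ValueError(f"detections table needs columns {sorted(required)}")
    frames_col = detections["frame"].to_numpy()
    if len(frames_col) and np.any(np.diff(frames_col) < 0):
        raise ValueError("detections must be ordered by frame")

    gate = params.gate_um
    if gate is None:
        gate = default_gate_um(params.interval_s, params.lateral_pitch_um)

    by_frame: dict[int, np.ndarray] = {
        int(f): g[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        for f, g in detections.groupby("frame", sort=True)
    }
    if not by_frame:
        return []
    f_min, f_max = min(by_frame), max(by_frame)

    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    for f in range(f_min, f_max + 1):
        pts = by_frame.get(f, np.empty((0, 3)))
        heads = open_tracks
        head_pos = (
            np.array([t.positions[-1] for t in heads])
            if heads
            else np.empty((0, 3))
        )
        pairs = link_frame_pair(head_pos, pts, gate) if f > f_min else []
        matched_heads = {i for i, _ in pairs}
        matched_pts = {j for _, j in pairs}
        for i, j in pairs:
            t = heads[i]
            if t.missed:  # fill single-frame gap with the midpoint
                t.frames.append(f - 1)
                t.positions.append(0.5 * (t.positions[-1] + pts[j]))
            t.frames.append(f)
            t.positions.append(pts[j])
            t.missed = 0
        still_open: list[_OpenTrack] = []
        for i, t in enumerate(heads):
            if i in matched_heads:
                still_open.append(t)
            else:
                t.missed += 1
                if t.missed > params.gap_closing:
                    closed.append(t)
                else:
                    still_open.append(t)
        open_tracks = still_open
        for j in range(len(pts)):
            if j not in matched_pts:
                t = _OpenTrack(frames=[f], positions=[pts[j]])
                open_tracks.append(t)
    closed.extend(open_tracks)

    survivors = [t for t in closed if len(t.frames) >= max(params.min_length, 2)]
    survivors.sort(
        key=lambda t: (t.frames[0], tuple(np.round(t.positions[0], 9)))
    )
    tracks = []
    for k, t in enumerate(survivors):
        tr = Track(
            id=k, start_frame=t.frames[0], positions_um=np.array(t.positions)
        )
        tr.mean_travel_speed = compute_mean_travel_speed(
            tr, params.interval_s, params.speed_definition
        )
        tracks.append(tr)
    return tracks


def compute_mean_travel_speed(
    track: Track, interval_s: float, definition: str = "path"
) -> float:
    """Mean travel speed in µm/s.

    ``"path"`` (default): summed consecutive step lengths over elapsed time —
    the per-step growth-rate semantics of EB1 analysis.  ``"net"``: start-to-
    end displacement over elapsed time.
    """
    if track.n_points < 2:
        raise ValueError("mean travel speed needs at least 2 points")
    elapsed = (track.n_points - 1) * interval_s
    if definition == "path":
        dist = float(np.sum(np.linalg.norm(np.diff(track.positions_um, axis=0), axis=1)))
    elif definition == "net":
        dist = float(np.linalg.norm(track.end_point_um - track.start_point_um))
    else:
        raise ValueError("definition must be 'path' or 'net'")
    return dist / elapsed


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Long-format table: track_id, cell_id, frame, x_um, y_um, z_um."""
    rows = {
        "track_id": [], "cell_id": [], "frame": [],
        "x_um": [], "y_um": [], "z_um": [],
    }
    for t in tracks:
        for f, p in zip(t.frames, t.positions_um):
            rows["track_id"].append(t.id)
            rows["cell_id"].append(t.cell_id)
            rows["frame"].append(int(f))
            rows["x_um"].append(p[0])
            rows["y_um"].append(p[1])
            rows["z_um"].append(p[2])
    return pd.DataFrame(rows)


def track_summary(tracks: list[Track], interval_s: float) -> pd.DataFrame:
    """Per-track summary with both speed definitions and endpoints."""
    rows = []
    for t in tracks:
        rows.append(
            {
                "track_id": t.id,
                "cell_id": t.cell_id,
                "n_points": t.n_points,
                "start_frame": int(t.start_frame),
                "mean_speed_um_s": compute_mean_travel_speed(t, interval_s, "path"),
                "net_speed_um_s": compute_mean_travel_speed(t, interval_s, "net"),
                "start_x_um": t.start_point_um[0],
                "start_y_um": t.start_point_um[1],
                "start_z_um": t.start_point_um[2],
                "end_x_um": t.end_point_um[0],
                "end_y_um": t.end_point_um[1],
                "end_z_um": t.end_point_um[2],
            }
        )
    return pd.DataFrame(rows)
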