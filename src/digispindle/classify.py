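"""Classification of registered trajectories by speed, zone, and travel angle.

Speed classes span 0–1 µm/s in 0.1 µm/s steps (10 classes by default).
Spatial classes are 10 concentric spherical shells ("zones") of equal radial
thickness around each centrosome, with sphere radius equal to the
intercentrosomal distance d; a trajectory belongs to the zone of its start
point around the nearer pole.  The travel angle is measured between the
trajectory's net displacement and the spindle axis, oriented from the
assigned pole toward the opposite pole (0–180 degrees); the undirected-axis
folding to 0–90 degrees is emitted as a derived column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import circstd

from .tracking import Track

__all__ = [
    "SpeedBinning",
    "ZonePartition",
    "ZoneAssignment",
    "AngleRecord",
    "bin_tracks_by_speed",
    "assign_zones",
    "compute_travel_angle",
    "zone_angle_summary",
    "subsample_tracks",
    "classification_table",
]

OUTSIDE = "outside"


@dataclass(frozen=True)
class SpeedBinning:
    """Half-open speed classes ``[lo, lo+width)``; the last includes its top."""

    lower: float = 0.0
    upper: float = 1.0
    width: float = 0.1

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        n = (self.upper - self.lower) / self.width
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("(upper - lower) must be a positive multiple of width")

    @property
    def n_bins(self) -> int:
        return int(round((self.upper - self.lower) / self.width))

    @property
    def edges(self) -> np.ndarray:
        return self.lower + self.width * np.arange(self.n_bins + 1)

    def bin_of(self, speed: float) -> int | None:
        """0-based bin index, or None when out of range."""
        if speed < self.lower or speed > self.upper:
            return None
        if speed == self.upper:
            return self.n_bins - 1
        # tolerate float error at the bin edges (0.3/0.1 == 2.999...)
        k = int(math.floor((speed - self.lower) / self.width + 1e-9))
        return min(k, self.n_bins - 1)


@dataclass(frozen=True)
class ZonePartition:
    """Concentric shells of equal thickness covering a sphere of radius d."""

    n_zones: int = 10
    radius_um: float = 10.0

    def __post_init__(self) -> None:
        if self.n_zones < 1:
            raise ValueError("n_zones must be a positive integer")
        if self.radius_um <= 0:
            raise ValueError("radius (intercentrosomal distance) must be positive")

    def zone_of(self, r_um: float) -> int | str:
        """1-based zone of a pole distance; r=0 → zone 1, r>d → "outside"."""
        if r_um < 0:
            raise ValueError("distance cannot be negative")
        if r_um > self.radius_um:
            return OUTSIDE
        if r_um == 0.0:
            return 1
        return min(
            int(math.ceil(self.n_zones * r_um / self.radius_um)), self.n_zones
        )


@dataclass(frozen=True)
class ZoneAssignment:
    track_id: int
    pole: int  # 1 or 2 (nearer centrosome; exact tie → 1)
    zone: int | str  # 1..n_zones or "outside"
    r_um: float


@dataclass(frozen=True)
class AngleRecord:
    track_id: int
    angle_deg: float  # vs pole→opposite-pole direction, 0..180; NaN if undefined
    zone: int | str

    @property
    def defined(self) -> bool:
        return not math.isnan(self.angle_deg)

    @property
    def angle_folded_deg(self) -> float:
        """Angle against the undirected axis, 0..90 degrees."""
        return min(self.angle_deg, 180.0 - self.angle_deg)


def bin_tracks_by_speed(
    tracks: list[Track], binning: SpeedBinning = SpeedBinning()
) -> tuple[dict[int, list[Track]], list[Track]]:
    """Group tracks into speed classes; returns (bin → tracks, out-of-range)."""
    groups: dict[int, list[Track]] = {k: [] for k in range(binning.n_bins)}
    out_of_range: list[Track] = []
    for t in tracks:
        k = binning.bin_of(t.mean_travel_speed)
        if k is None:
            out_of_range.append(t)
        else:
            groups[k].append(t)
    return groups, out_of_range


def assign_zones(
    tracks: list[Track],
    partition: ZonePartition,
    pole1_um: np.ndarray,
    pole2_um: np.ndarray,
) -> list[ZoneAssignment]:
    """Assign each track to the spherical zone of its start point.

    The start point's distances to both poles are compared; the nearer pole
    (tie → pole 1) owns the trajectory, and its zone is
    ``ceil(n_zones * r / d)`` with r = distance to that pole.
    """
    p1 = np.asarray(pole1_um, dtype=float)
    p2 = np.asarray(pole2_um, dtype=float)
    out = []
    for t in tracks:
        r1 = float(np.linalg.norm(t.start_point_um - p1))
        r2 = float(np.linalg.norm(t.start_point_um - p2))
        pole, r = (1, r1) if r1 <= r2 else (2, r2)
        out.append(
            ZoneAssignment(track_id=t.id, pole=pole, zone=partition.zone_of(r), r_um=r)
        )
    return out


def compute_travel_angle(
    track: Track, pole: int, pole1_um: np.ndarray, pole2_um: np.ndarray,
    zone: int | str = -1,
) -> AngleRecord:
    """Angle between a track's net displacement and its outward spindle axis.

    The reference direction points from the assigned pole toward the opposite
    pole.  A zero net displacement leaves the angle undefined (NaN record,
    excluded from summaries).
    """
    if pole not in (1, 2):
        raise ValueError("pole must be 1 or 2")
    axis = (
        np.asarray(pole2_um, float) - np.asarray(pole1_um, float)
        if pole == 1
        else np.asarray(pole1_um, float) - np.asarray(pole2_um, float)
    )
    disp = track.end_point_um - track.start_point_um
    norm = np.linalg.norm(disp) * np.linalg.norm(axis)
    if norm < 1e-15:
        return AngleRecord(track_id=track.id, angle_deg=float("nan"), zone=zone)
    cosang = float(np.clip(np.dot(disp, axis) / norm, -1.0, 1.0))
    return AngleRecord(
        track_id=track.id, angle_deg=math.degrees(math.acos(cosang)), zone=zone
    )


def zone_angle_summary(
    records: list[AngleRecord], bin_width_deg: float = 10.0
) -> pd.DataFrame:
    """Per-zone angle statistics: count, mean, circular sd, 10-degree histogram.

    Undefined (NaN) angles are excluded.  Histogram columns are
    ``hist_0_10`` … ``hist_170_180``.
    """
    defined = [r for r in records if r.defined]
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    rows = []
    zones = sorted({r.zone for r in defined}, key=lambda z: (isinstance(z, str), z))
    for z in zones:
        angles = np.array([r.angle_deg for r in defined if r.zone == z])
        hist, _ = np.histogram(angles, bins=edges)
        row = {
            "zone": z,
            "count": len(angles),
            "mean_angle_deg": float(np.mean(angles)),
            "circ_sd_deg": float(
                np.degrees(circstd(np.radians(angles), high=2 * np.pi, low=0.0))
            ),
        }
        for i in range(len(edges) - 1):
            row[f"hist_{int(edges[i])}_{int(edges[i + 1])}"] = int(hist[i])
        rows.append(row)
    return pd.DataFrame(rows)


def subsample_tracks(tracks: list[Track], fraction: float, seed: int) -> list[Track]:
    """Uniform random subset of ``round(fraction * n)`` tracks, seed-stable."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(tracks)
    n_keep = int(round(fraction * len(tracks)))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(tracks), size=n_keep, replace=False))
    return [tracks[i] for i in idx]


def classification_table(
    tracks: list[Track],
    assignments: list[ZoneAssignment],
    angles: list[AngleRecord],
    binning: SpeedBinning = SpeedBinning(),
) -> pd.DataFrame:
    """Combined per-track classification table (one row per track)."""
    by_id_zone = {a.track_id: a for a in assignments}
    by_id_angle = {r.track_id: r for r in angles}
    rows = []
    for t in tracks:
        a = by_id_zone[t.id]
        r = by_id_angle.get(t.id)
        k = binning.bin_of(t.mean_travel_speed)
        rows.append(
            {
                "track_id": t.id,
                "cell_id": t.cell_id,
                "speed_um_s": t.mean_travel_speed,
                "speed_bin": -1 if k is None else k + 1,
                "pole": a.pole,
                "zone": a.zone,
                "r_start_um": a.r_um,
                "angle_deg": float("nan") if r is None else r.angle_deg,
                "angle_folded_deg": float("nan")
                if r is None or not r.defined
                else r.angle_folded_deg,
            }
        )
    return pd.DataFrame(rows)
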