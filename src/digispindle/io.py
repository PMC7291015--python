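"""File formats: CSV tables, OME-TIFF volume series, YAML run configuration.

All files carry physical units (µm, s, degrees); no pixel-unit files are
written.  CSV writing is deterministic (fixed column order, ``%.9g`` floats)
so identical runs produce byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .models import AcquisitionSpec, GroundTruthTrajectory, SpindleGeometryTrack
from .tracking import Track

__all__ = [
    "write_csv",
    "ground_truth_table",
    "trajectories_as_detections",
    "centrosome_table",
    "read_centrosome_table",
    "tracks_from_frame",
    "write_ome_tiff",
    "read_ome_tiff",
    "load_config",
    "dump_config",
]

_FLOAT_FMT = "%.9g"


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV write (no index, fixed float format, LF endings)."""
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def ground_truth_table(
    trajectories: Sequence[GroundTruthTrajectory], phase: str
) -> pd.DataFrame:
    """Long-format ground truth: id, frame, x/y/z_um, speed, zone_true, phase."""
    rows = {
        "id": [], "frame": [], "x_um": [], "y_um": [], "z_um": [],
        "speed_um_per_s": [], "zone_true": [], "phase": [],
    }
    for tr in trajectories:
        for f, p in zip(tr.frames, tr.positions_um):
            rows["id"].append(tr.id)
            rows["frame"].append(int(f))
            rows["x_um"].append(p[0])
            rows["y_um"].append(p[1])
            rows["z_um"].append(p[2])
            rows["speed_um_per_s"].append(tr.true_mean_speed)
            rows["zone_true"].append(tr.zone_true)
            rows["phase"].append(phase)
    return pd.DataFrame(rows)


def trajectories_as_detections(
    trajectories: Sequence[GroundTruthTrajectory],
) -> pd.DataFrame:
    """Ground-truth positions in detection-table form (oracle detector bypass)."""
    rows = {"frame": [], "x_um": [], "y_um": [], "z_um": [],
            "intensity": [], "response": []}
    for tr in trajectories:
        for f, p in zip(tr.frames, tr.positions_um):
            rows["frame"].append(int(f))
            rows["x_um"].append(p[0])
            rows["y_um"].append(p[1])
            rows["z_um"].append(p[2])
            rows["intensity"].append(1.0)
            rows["response"].append(1.0)
    df = pd.DataFrame(rows)
    return df.sort_values(["frame", "x_um", "y_um", "z_um"], kind="stable").reset_index(
        drop=True
    )


def centrosome_table(geometry: SpindleGeometryTrack) -> pd.DataFrame:
    """Centrosome CSV schema: frame, pole (1|2), x_um, y_um, z_um."""
    n = geometry.n_frames
    frames = np.repeat(np.arange(n), 2)
    poles = np.tile([1, 2], n)
    pos = np.empty((2 * n, 3))
    pos[0::2] = geometry.centrosome1_um
    pos[1::2] = geometry.centrosome2_um
    return pd.DataFrame(
        {
            "frame": frames,
            "pole": poles,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
        }
    )


def read_centrosome_table(
    df_or_path: pd.DataFrame | str | Path, phase: str = "unknown"
) -> SpindleGeometryTrack:
    """Build a geometry track from a centrosome table (pole identity fixed
    at frame 0 and propagated by proximity to prevent axis flips)."""
    df = (
        df_or_path
        if isinstance(df_or_path, pd.DataFrame)
        else pd.read_csv(df_or_path)
    )
    frames = np.sort(df["frame"].unique())
    expected = np.arange(frames.min(), frames.max() + 1)
    missing = sorted(int(f) for f in set(expected) - set(frames))
    if missing:
        raise ValueError(f"frames missing centrosome data: {missing}")
    c1 = np.empty((len(frames), 3))
    c2 = np.empty((len(frames), 3))
    prev1 = None
    for i, f in enumerate(frames):
        g = df[df["frame"] == f]
        if len(g) != 2:
            raise ValueError(f"frame {f} must have exactly two centrosome rows")
        a = g.sort_values("pole")[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        if prev1 is not None and np.linalg.norm(a[0] - prev1) > np.linalg.norm(
            a[1] - prev1
        ):
            a = a[::-1]
        c1[i], c2[i] = a
        prev1 = c1[i]
    return SpindleGeometryTrack(phase, c1, c2)


def tracks_from_frame(df: pd.DataFrame, interval_s: float) -> list[Track]:
    """Rebuild Track objects from a long-format tracks table."""
    from .tracking import compute_mean_travel_speed

    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        t = Track(
            id=int(tid),
            start_frame=int(g["frame"].iloc[0]),
            positions_um=g[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
            cell_id=str(g["cell_id"].iloc[0]) if "cell_id" in g else "cell0",
        )
        t.mean_travel_speed = compute_mean_travel_speed(t, interval_s)
        tracks.append(t)
    return tracks


def write_ome_tiff(
    path: str | Path,
    volumes: Sequence[np.ndarray] | np.ndarray,
    acquisition: AcquisitionSpec,
) -> None:
    """Write a (t, z, y, x) series as OME-TIFF with physical metadata.

    PhysicalSizeX/Y/Z carry the voxel pitch in µm and TimeIncrement the
    volume interval in seconds.
    """
    data = np.asarray(volumes, dtype=np.float32)
    if data.ndim == 3:
        data = data[None]
    px, py, pz = acquisition.voxel_pitch_um
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "TZYX",
            "PhysicalSizeX": px,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": py,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": pz,
            "PhysicalSizeZUnit": "µm",
            "TimeIncrement": acquisition.interval_s,
            "TimeIncrementUnit": "s",
        },
    )


def read_ome_tiff(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an OME-TIFF series; returns ``(t, z, y, x)`` data and metadata.

    Metadata keys: voxel_pitch_um (x, y, z) and interval_s when present.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta: dict = {}
        if tif.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            pixels = root.find(".//ome:Pixels", ns)
            if pixels is not None:
                get = pixels.attrib.get
                if get("PhysicalSizeX"):
                    meta["voxel_pitch_um"] = (
                        float(get("PhysicalSizeX")),
                        float(get("PhysicalSizeY", get("PhysicalSizeX"))),
                        float(get("PhysicalSizeZ", get("PhysicalSizeX"))),
                    )
                if get("TimeIncrement"):
                    meta["interval_s"] = float(get("TimeIncrement"))
    if data.ndim == 3:
        data = data[None]
    return data, meta


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (validated by :mod:`digispindle.pipeline`)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a YAML mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
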