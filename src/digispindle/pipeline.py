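"""End-to-end pipeline: simulate → render → detect → track → register → classify.

A run is described by a small YAML configuration with per-stage blocks;
unknown keys are rejected so typos fail loudly.  One global seed
deterministically derives independent substreams for the geometry,
trajectory, rendering and subsampling stages, so a stage can be re-run in
isolation without disturbing the others.  Every run writes its fully
resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as dio
from .classify import (
    SpeedBinning,
    ZonePartition,
    assign_zones,
    bin_tracks_by_speed,
    classification_table,
    compute_travel_angle,
    subsample_tracks,
    zone_angle_summary,
)
from .detect import (
    DetectionParams,
    detect_comets,
    detections_to_frame,
    exclude_near,
    suppress_foci,
)
from .models import (
    AcquisitionSpec,
    CometModel,
    GeometryModel,
    MotionModel,
    OpticsModel,
    SimulationConfig,
)
from .register import register_series
from .render import render_volume_series
from .simulate import make_phase_preset, simulate_geometry, simulate_trajectories
from .tracking import TrackingParams, build_tracks, track_summary, tracks_to_frame

__all__ = ["SCHEMA_VERSION", "validate_config", "resolve_simulation", "run_pipeline"]

SCHEMA_VERSION = "1"
log = logging.getLogger("digispindle")

_STAGE_KEYS: dict[str, set[str]] = {
    "": {"schema_version", "seed", "scale", "phase", "simulate", "render",
         "detect", "track", "register", "classify", "inputs"},
    "simulate": {"acquisition", "optics", "comet", "geometry", "motion"},
    "render": {"noise", "write_volumes"},
    "detect": {"threshold_k", "threshold_abs", "min_sep_um", "use_ground_truth",
               "pole_suppression", "pole_exclusion_um"},
    "track": {"gate_um", "min_length", "gap_closing", "speed_definition"},
    "register": {"enabled"},
    "classify": {"n_zones", "bin_lower", "bin_upper", "bin_width",
                 "subsample_fraction"},
    "inputs": {"detections", "centrosomes"},
}
_SIM_BLOCKS = {
    "acquisition": AcquisitionSpec,
    "optics": OpticsModel,
    "comet": CometModel,
    "geometry": GeometryModel,
    "motion": MotionModel,
}


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(
            f"unknown configuration key(s) {sorted(unknown)} in {where or 'top level'}"
        )


def validate_config(cfg: dict) -> dict:
    """Validate a run configuration dict; returns it with defaults filled."""
    cfg = dict(cfg)
    _check_keys(cfg, _STAGE_KEYS[""], "")
    version = str(cfg.setdefault("schema_version", SCHEMA_VERSION))
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version!r}")
    cfg.setdefault("seed", 0)
    cfg.setdefault("scale", "desk")
    cfg.setdefault("phase", "metaphase")
    for stage in ("simulate", "render", "detect", "track", "register",
                  "classify", "inputs"):
        block = cfg.setdefault(stage, {})
        if not isinstance(block, dict):
            raise ValueError(f"stage block {stage!r} must be a mapping")
        _check_keys(block, _STAGE_KEYS[stage], stage)
    sim = cfg["simulate"]
    for name, block in sim.items():
        cls = _SIM_BLOCKS[name]
        fields = {f.name for f in dataclasses.fields(cls)}
        _check_keys(block, fields, f"simulate.{name}")
    return cfg


def resolve_simulation(cfg: dict) -> SimulationConfig:
    """Phase preset for the configured phase/scale with overrides applied."""
    sim = make_phase_preset(cfg["phase"], cfg["scale"])
    for name, block in cfg["simulate"].items():
        if not block:
            continue
        current = getattr(sim, name)
        values = {
            k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
        }
        sim = sim.with_(**{name: dataclasses.replace(current, **values)})
    return sim


def _substreams(seed: int, n: int = 4) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict[str, Any]:
    """Execute the configured stages and write all tables under ``out_dir``.

    Returns a dict with per-stage objects and counts (geometry, trajectories,
    detections, tracks, registered tracks, classification tables).
    """
    cfg = validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _substreams(int(cfg["seed"]))
    sim = resolve_simulation(cfg)
    acq = sim.acquisition
    result: dict[str, Any] = {"config": cfg, "simulation": sim}

    inputs = cfg["inputs"]
    trajectories = None
    if inputs.get("detections"):
        det_path = Path(inputs["detections"])
        if not det_path.exists():
            raise FileNotFoundError(
                f"stage 'detect' input missing: expected detections CSV {det_path}"
            )
        if not inputs.get("centrosomes"):
            raise ValueError(
                "stage 'register' input missing: supply inputs.centrosomes "
                "alongside inputs.detections"
            )
        detections = pd.read_csv(det_path)
        geometry = dio.read_centrosome_table(inputs["centrosomes"], cfg["phase"])
        log.info("loaded %d detections from %s", len(detections), det_path)
    else:
        geometry = simulate_geometry(sim, seeds[0])
        trajectories = simulate_trajectories(sim, geometry, seeds[1])
        log.info(
            "simulated %d trajectories (%d comet observations) in phase %s",
            len(trajectories),
            sum(t.n_points for t in trajectories),
            sim.phase,
        )
        dio.write_csv(
            dio.ground_truth_table(trajectories, sim.phase), out / "ground_truth.csv"
        )
        dio.write_csv(dio.centrosome_table(geometry), out / "centrosomes.csv")

        if cfg["detect"].get("use_ground_truth"):
            detections = dio.trajectories_as_detections(trajectories)
            log.info("detector bypassed: %d ground-truth detections", len(detections))
        else:
            noise = bool(cfg["render"].get("noise", True))
            params = DetectionParams(
                target_fwhm_um=(
                    sim.optics.fwhm_lateral_nm * 1e-3,
                    sim.optics.fwhm_lateral_nm * 1e-3,
                    sim.optics.fwhm_axial_nm * 1e-3,
                ),
                threshold_k=float(cfg["detect"].get("threshold_k", 8.0)),
                threshold_abs=cfg["detect"].get("threshold_abs"),
                min_separation_um=float(cfg["detect"].get("min_sep_um", 0.5)),
            )
            pole_suppression = bool(cfg["detect"].get("pole_suppression", True))
            pole_exclusion = float(cfg["detect"].get("pole_exclusion_um", 0.3))
            frames = []
            volumes = [] if cfg["render"].get("write_volumes") else None
            for f, vol in render_volume_series(
                trajectories, geometry, sim.optics, sim.comet, acq,
                seed=seeds[2], noise=noise,
            ):
                if volumes is not None:
                    volumes.append(vol)
                foci = np.stack(
                    [geometry.centrosome1_um[f], geometry.centrosome2_um[f]]
                )
                if pole_suppression:
                    vol = suppress_foci(vol, foci, sim.optics.sigma_um,
                                        acq.voxel_pitch_um)
                dets = detect_comets(vol, acq.voxel_pitch_um, params, frame=f)
                if pole_exclusion > 0:
                    dets = exclude_near(dets, foci, pole_exclusion)
                frames.extend(dets)
            if volumes is not None:
                dio.write_ome_tiff(out / "volumes.ome.tif", np.stack(volumes), acq)
            detections = detections_to_frame(frames)
            detections = detections.sort_values(
                ["frame", "x_um", "y_um", "z_um"], kind="stable"
            ).reset_index(drop=True)
            log.info("detected %d comets over %d frames", len(detections), acq.n_frames)
    dio.write_csv(detections, out / "detections.csv")
    result["geometry"] = geometry
    result["trajectories"] = trajectories
    result["detections"] = detections
    result["n_detections"] = len(detections)

    tparams = TrackingParams(
        gate_um=cfg["track"].get("gate_um"),
        min_length=int(cfg["track"].get("min_length", 4)),
        gap_closing=int(cfg["track"].get("gap_closing", 0)),
        speed_definition=cfg["track"].get("speed_definition", "path"),
        interval_s=acq.interval_s,
        lateral_pitch_um=acq.voxel_pitch_um[0],
    )
    tracks = build_tracks(detections, tparams)
    log.info("linked %d tracks (min length %d)", len(tracks), tparams.min_length)
    dio.write_csv(tracks_to_frame(tracks), out / "tracks.csv")
    dio.write_csv(track_summary(tracks, acq.interval_s), out / "track_summary.csv")
    result["tracks"] = tracks
    result["n_tracks"] = len(tracks)

    registered, reg_geometry, _ = register_series(tracks, geometry, acq.interval_s)
    reg_df = tracks_to_frame(registered)
    dio.write_csv(reg_df, out / "registered_tracks.csv")
    result["registered_tracks"] = registered
    result["registered_geometry"] = reg_geometry

    cls_cfg = cfg["classify"]
    frac = cls_cfg.get("subsample_fraction")
    selected = (
        subsample_tracks(registered, float(frac), seeds[3]) if frac else registered
    )
    d_mean = float(np.mean(reg_geometry.d_um))
    partition = ZonePartition(
        n_zones=int(cls_cfg.get("n_zones", 10)), radius_um=d_mean
    )
    pole1 = np.array([-0.5 * d_mean, 0.0, 0.0])
    pole2 = np.array([0.5 * d_mean, 0.0, 0.0])
    assignments = assign_zones(selected, partition, pole1, pole2)
    zone_by_id = {a.track_id: a for a in assignments}
    angles = [
        compute_travel_angle(t, zone_by_id[t.id].pole, pole1, pole2,
                             zone=zone_by_id[t.id].zone)
        for t in selected
    ]
    binning = SpeedBinning(
        lower=float(cls_cfg.get("bin_lower", 0.0)),
        upper=float(cls_cfg.get("bin_upper", 1.0)),
        width=float(cls_cfg.get("bin_width", 0.1)),
    )
    groups, out_of_range = bin_tracks_by_speed(selected, binning)
    cls_table = classification_table(selected, assignments, angles, binning)
    dio.write_csv(cls_table, out / "classification.csv")
    bins_df = pd.DataFrame(
        {
            "bin": np.arange(1, binning.n_bins + 1),
            "lower_um_s": binning.edges[:-1],
            "upper_um_s": binning.edges[1:],
            "count": [len(groups[k]) for k in range(binning.n_bins)],
        }
    )
    dio.write_csv(bins_df, out / "speed_bins.csv")
    dio.write_csv(zone_angle_summary(angles), out / "zone_summary.csv")
    log.info(
        "classified %d tracks (%d out of speed range)", len(selected),
        len(out_of_range),
    )
    result["classification"] = cls_table
    result["speed_bins"] = bins_df
    result["angles"] = angles
    result["assignments"] = assignments
    result["d_mean_um"] = d_mean

    dio.dump_config(cfg, out / "resolved_config.yaml")
    return result
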