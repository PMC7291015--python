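"""Rendering of LLSM-like 3D+t fluorescence volumes from ground truth.

Each comet is a tip-anchored emitter: a train of point samples extending at
most ``tail_length_nm`` behind the tip along the reversed instantaneous
velocity, with exponentially decaying weights.  Every sample is blurred by a
separable Gaussian PSF (lateral/axial FWHMs from the optics model, the 25 nm
comet cross-section added in quadrature) and sampled onto the voxel grid at
voxel centres.  Signal bleaches as ``exp(-bleach_rate * t)``; Poisson shot
noise is applied to signal plus background, then zero-mean Gaussian read
noise, and the result is clamped at zero.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np

from .models import (
    AcquisitionSpec,
    CometModel,
    FWHM_TO_SIGMA,
    GroundTruthTrajectory,
    OpticsModel,
    SpindleGeometryTrack,
)

__all__ = [
    "render_frame",
    "render_volume_series",
    "render_series_array",
    "measure_fwhm",
    "CENTROSOME_BRIGHTNESS",
]

#: Centrosome focus amplitude relative to the comet peak signal.
CENTROSOME_BRIGHTNESS = 5.0


def _effective_sigma_um(optics: OpticsModel, comet: CometModel) -> np.ndarray:
    """Per-axis (x, y, z) Gaussian sigma of PSF ⊗ comet cross-section, µm."""
    psf = np.asarray(optics.sigma_um)
    cross = comet.short_axis_diameter_nm * 1e-3 * FWHM_TO_SIGMA
    return np.sqrt(psf**2 + cross**2)


def _splat(
    volume: np.ndarray,
    centers_um: np.ndarray,
    weights: np.ndarray,
    sigma_um: np.ndarray,
    pitch_um: Sequence[float],
) -> None:
    """Add normalised Gaussians (total photons = sum of weights) in place.

    ``volume`` is (z, y, x); ``centers_um`` is (k, 3) xyz.  Each Gaussian is
    evaluated at voxel centres and scaled so its infinite-grid sum equals its
    weight (voxel volume over the Gaussian normalisation).
    """
    pitch = np.asarray(pitch_um, dtype=float)  # (x, y, z)
    nz, ny, nx = volume.shape
    dims = np.array([nx, ny, nz])
    half_extent = 4.0 * sigma_um
    lo_um = centers_um.min(axis=0) - half_extent
    hi_um = centers_um.max(axis=0) + half_extent
    lo = np.maximum(np.floor(lo_um / pitch).astype(int), 0)
    hi = np.minimum(np.ceil(hi_um / pitch).astype(int) + 1, dims)
    if np.any(lo >= hi):
        return
    norm = np.prod(pitch) / np.prod(sigma_um * np.sqrt(2.0 * np.pi))
    axes = [np.arange(lo[a], hi[a]) * pitch[a] for a in range(3)]  # x, y, z
    # squared z/y/x offsets, broadcast (z, y, x, k)
    exps = []
    for a, grid in enumerate(axes):
        d = (grid[:, None] - centers_um[None, :, a]) / sigma_um[a]
        exps.append(0.5 * d * d)
    e = (
        exps[2][:, None, None, :]
        + exps[1][None, :, None, :]
        + exps[0][None, None, :, :]
    )
    patch = norm * np.exp(-e) @ weights
    volume[lo[2] : hi[2], lo[1] : hi[1], lo[0] : hi[0]] += patch.astype(
        volume.dtype
    )


def _comet_samples(
    tip_um: np.ndarray,
    velocity_um: np.ndarray,
    comet: CometModel,
    sample_step_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample points and relative weights of one comet's tail profile."""
    speed = float(np.linalg.norm(velocity_um))
    tail_um = comet.tail_length_nm * 1e-3
    if speed < 1e-12:
        return tip_um[None, :], np.array([1.0])
    back = -velocity_um / speed
    n = max(int(np.floor(tail_um / sample_step_um)) + 1, 2)
    s = np.linspace(0.0, tail_um, n)
    w = np.exp(-comet.tail_decay * s / tail_um)
    return tip_um[None, :] + s[:, None] * back[None, :], w


def _alive_at(
    trajectories: Sequence[GroundTruthTrajectory], frame: int
) -> list[tuple[GroundTruthTrajectory, int]]:
    out = []
    for tr in trajectories:
        k = frame - tr.start_frame
        if 0 <= k < tr.n_points:
            out.append((tr, k))
    return out


def render_frame(
    frame: int,
    trajectories: Sequence[GroundTruthTrajectory],
    geometry: SpindleGeometryTrack | None,
    optics: OpticsModel,
    comet: CometModel,
    acquisition: AcquisitionSpec,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Render one 3D volume (z, y, x, float32) at the given frame index."""
    nz, ny, nx = acquisition.grid_shape
    volume = np.zeros((nz, ny, nx), dtype=np.float32)
    pitch = np.asarray(acquisition.voxel_pitch_um)
    sigma = _effective_sigma_um(optics, comet)
    bleach = np.exp(-optics.bleach_rate_per_s * frame * acquisition.interval_s)
    step = 0.5 * float(pitch.min())

    for tr, k in _alive_at(trajectories, frame):
        pos = tr.positions_um
        vel = pos[min(k + 1, tr.n_points - 1)] - pos[min(k + 1, tr.n_points - 1) - 1]
        centers, w = _comet_samples(pos[k], vel, comet, step)
        w = w * (optics.peak_signal * bleach / w.sum())
        _splat(volume, centers, w, sigma, pitch)

    if geometry is not None:
        foci = np.stack(
            [geometry.centrosome1_um[frame], geometry.centrosome2_um[frame]]
        )
        amp = CENTROSOME_BRIGHTNESS * optics.peak_signal * bleach
        _splat(volume, foci, np.array([amp, amp]), np.asarray(optics.sigma_um), pitch)

    volume += optics.background_level
    if noise:
        if rng is None:
            rng = np.random.default_rng()
        volume = rng.poisson(volume).astype(np.float32)
        if optics.read_noise_sd > 0:
            volume += rng.normal(0.0, optics.read_noise_sd, volume.shape).astype(
                np.float32
            )
        np.clip(volume, 0.0, None, out=volume)
    return volume


def render_volume_series(
    trajectories: Sequence[GroundTruthTrajectory],
    geometry: SpindleGeometryTrack | None,
    optics: OpticsModel,
    comet: CometModel,
    acquisition: AcquisitionSpec,
    seed: int = 0,
    noise: bool = True,
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield ``(frame_index, volume)`` for every frame of the acquisition.

    Volumes are generated lazily so long series never have to be held in
    memory at once.  All trajectory positions must lie inside the field of
    view (the simulator guarantees this; external tables are validated).
    """
    for tr in trajectories:
        if not np.all(acquisition.contains(tr.positions_um)):
            raise ValueError(
                f"trajectory {tr.id} has positions outside the field of view"
            )
    rng = np.random.default_rng(seed)
    for frame in range(acquisition.n_frames):
        yield frame, render_frame(
            frame, trajectories, geometry, optics, comet, acquisition, rng, noise
        )


def render_series_array(*args, **kwargs) -> np.ndarray:
    """Render the whole series into one (t, z, y, x) array (small runs only)."""
    return np.stack([vol for _, vol in render_volume_series(*args, **kwargs)])


def measure_fwhm(
    volume: np.ndarray,
    voxel_pitch_um: Sequence[float],
    axis: str,
) -> float:
    """Full width at half maximum (µm) of the through-peak profile.

    ``axis`` is ``"x"``, ``"y"`` or ``"z"``.  The 1D profile through the
    global intensity maximum is baseline-subtracted (profile minimum) and the
    two half-maximum crossings are located by linear interpolation.
    """
    ax = {"x": 2, "y": 1, "z": 0}[axis]
    peak = np.unravel_index(int(np.argmax(volume)), volume.shape)
    index: list = list(peak)
    index[ax] = slice(None)
    profile = np.asarray(volume[tuple(index)], dtype=float)
    profile = profile - profile.min()
    pk = int(np.argmax(profile))
    half = profile[pk] / 2.0

    def _crossing(lo_side: bool) -> float:
        idx = range(pk, -1, -1) if lo_side else range(pk, len(profile))
        prev = pk
        for i in idx:
            if profile[i] < half:
                f = (profile[prev] - half) / (profile[prev] - profile[i])
                return prev + (i - prev) * f
            prev = i
        raise ValueError("profile does not fall below half maximum inside the volume")

    pitch = (voxel_pitch_um[0], voxel_pitch_um[1], voxel_pitch_um[2])[
        {"x": 0, "y": 1, "z": 2}[axis]
    ]
    return (_crossing(False) - _crossing(True)) * pitch
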