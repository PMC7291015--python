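"""Domain types for the digital-spindle pipeline.

All spatial quantities are physical: distances in micrometres (µm), times in
seconds, angles in degrees.  Volume arrays are indexed ``(z, y, x)`` in voxel
order with the position ``(0, 0, 0)`` at the centre of the first voxel, so a
voxel index ``i`` along an axis corresponds to the physical coordinate
``i * pitch`` along that axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AcquisitionSpec",
    "OpticsModel",
    "CometModel",
    "GeometryModel",
    "MotionModel",
    "SimulationConfig",
    "SpindleGeometryTrack",
    "GroundTruthTrajectory",
    "FWHM_TO_SIGMA",
]

#: FWHM = 2 * sqrt(2 ln 2) * sigma for a Gaussian profile.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class AcquisitionSpec:
    """Time and space sampling of a volumetric time-lapse acquisition.

    Parameters
    ----------
    n_frames : int
        Number of 3D volumes in the series.
    interval_s : float
        Time between consecutive volumes, seconds.
    voxel_pitch_um : tuple of float
        Voxel pitch ``(x, y, z)`` in µm.
    fov_extent_um : tuple of float
        Physical extent of the field of view ``(x, y, z)`` in µm.
    """

    n_frames: int = 75
    interval_s: float = 0.755
    voxel_pitch_um: tuple[float, float, float] = (0.104, 0.104, 0.2)
    fov_extent_um: tuple[float, float, float] = (32.0, 22.0, 22.0)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be a positive integer")
        if self.interval_s <= 0:
            raise ValueError("interval_s must be positive")
        if len(self.voxel_pitch_um) != 3 or len(self.fov_extent_um) != 3:
            raise ValueError("voxel_pitch_um and fov_extent_um need 3 entries")
        if any(p <= 0 for p in self.voxel_pitch_um):
            raise ValueError("voxel pitches must be strictly positive")
        if any(e <= 0 for e in self.fov_extent_um):
            raise ValueError("field-of-view extents must be strictly positive")
        if any(p > e for p, e in zip(self.voxel_pitch_um, self.fov_extent_um)):
            raise ValueError("voxel pitch larger than the field of view")

    @property
    def duration_s(self) -> float:
        """Total duration: ``n_frames * interval_s`` seconds."""
        return self.n_frames * self.interval_s

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Voxel grid shape ``(nz, ny, nx)`` (extent / pitch, rounded up)."""
        nx, ny, nz = (
            int(math.ceil(e / p))
            for e, p in zip(self.fov_extent_um, self.voxel_pitch_um)
        )
        return (nz, ny, nx)

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.interval_s

    def contains(self, positions_um: np.ndarray) -> np.ndarray:
        """True for each (..., 3) xyz position inside the sampled grid."""
        p = np.asarray(positions_um, dtype=float)
        nz, ny, nx = self.grid_shape
        hi = np.array(
            [
                (nx - 1) * self.voxel_pitch_um[0],
                (ny - 1) * self.voxel_pitch_um[1],
                (nz - 1) * self.voxel_pitch_um[2],
            ]
        )
        return np.all((p >= 0.0) & (p <= hi), axis=-1)


@dataclass(frozen=True)
class OpticsModel:
    """Imaging model of a dithered-mode lattice light-sheet microscope.

    The point-spread function is a separable Gaussian with the configured
    lateral (x, y) and axial (z) full widths at half maximum.  Signal photons
    are drawn from a Poisson law on top of a uniform background and read out
    with additive zero-mean Gaussian noise; the signal (not the background)
    bleaches exponentially with ``bleach_rate_per_s``.
    """

    fwhm_lateral_nm: float = 230.0
    fwhm_axial_nm: float = 370.0
    background_level: float = 10.0
    peak_signal: float = 1000.0
    read_noise_sd: float = 1.5
    bleach_rate_per_s: float = 0.005

    def __post_init__(self) -> None:
        if self.fwhm_lateral_nm <= 0 or self.fwhm_axial_nm <= 0:
            raise ValueError("PSF FWHMs must be positive")
        if self.fwhm_axial_nm < self.fwhm_lateral_nm:
            warnings.warn(
                "axial FWHM below lateral FWHM is unusual for light-sheet optics",
                stacklevel=2,
            )
        for name in ("background_level", "read_noise_sd", "bleach_rate_per_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.peak_signal <= 0:
            raise ValueError("peak_signal must be positive")

    @property
    def sigma_um(self) -> tuple[float, float, float]:
        """PSF Gaussian sigma ``(x, y, z)`` in µm."""
        lat = self.fwhm_lateral_nm * 1e-3 * FWHM_TO_SIGMA
        ax = self.fwhm_axial_nm * 1e-3 * FWHM_TO_SIGMA
        return (lat, lat, ax)


@dataclass(frozen=True)
class CometModel:
    """Geometry of an EB1 comet: a narrow tip with a decaying tail.

    The tail intensity falls off as ``exp(-tail_decay * s / tail_length_nm)``
    with distance ``s`` behind the tip along the (reversed) velocity vector and
    is truncated at ``tail_length_nm``.
    """

    short_axis_diameter_nm: float = 25.0
    tail_length_nm: float = 500.0
    tail_decay: float = 3.0

    def __post_init__(self) -> None:
        if self.short_axis_diameter_nm <= 0:
            raise ValueError("short_axis_diameter_nm must be positive")
        if self.tail_length_nm < self.short_axis_diameter_nm:
            raise ValueError("tail_length_nm must be >= short_axis_diameter_nm")
        if self.tail_decay <= 0:
            raise ValueError("tail_decay must be positive")


@dataclass(frozen=True)
class GeometryModel:
    """Spindle geometry and its slow rigid drift.

    The two centrosomes sit at ``(-d/2, 0, 0)`` and ``(+d/2, 0, 0)`` in the
    spindle's own frame.  The whole spindle translates with a constant random
    drift velocity of magnitude ``drift_translation_um_per_s`` and rotates
    about its midpoint around a random fixed axis at
    ``drift_rotation_deg_per_s``; the intercentrosomal distance changes
    linearly at ``separation_rate_um_per_s`` (pole separation in anaphase).
    ``center_um = None`` places the spindle at the centre of the field of view.
    """

    d_um: float = 10.0
    center_um: tuple[float, float, float] | None = None
    initial_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    drift_translation_um_per_s: float = 0.02
    drift_rotation_deg_per_s: float = 0.2
    drift_rotation_axis: tuple[float, float, float] | None = None  # None = random
    separation_rate_um_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.d_um <= 0:
            raise ValueError("intercentrosomal distance d_um must be positive")
        if np.linalg.norm(self.initial_axis) == 0:
            raise ValueError("initial_axis must be a nonzero vector")
        if self.drift_translation_um_per_s < 0 or self.drift_rotation_deg_per_s < 0:
            raise ValueError("drift magnitudes must be non-negative")


def _default_speed_means() -> tuple[float, ...]:
    # Pole-proximal comets grow faster in the defaults; linear 0.55 -> 0.35.
    return tuple(np.round(np.linspace(0.55, 0.35, 10), 6))


def _default_birth_weights() -> tuple[float, ...]:
    return (0.20, 0.17, 0.14, 0.12, 0.10, 0.08, 0.07, 0.05, 0.04, 0.03)


@dataclass(frozen=True)
class MotionModel:
    """Kinematic model of comet trajectories.

    Births follow a Poisson process in time at ``birth_rate_per_s``; each
    birth picks a pole (equal probability), a spherical zone around that pole
    with probability ``birth_density_by_zone``, then a start position uniform
    in that shell.  A trajectory moves in a straight line with a constant
    speed drawn from ``Normal(speed_mean_by_zone[zone], speed_sd)`` clipped to
    [0, 1] µm/s, in a direction drawn from a von Mises–Fisher law about the
    outward spindle-axis direction with concentration
    ``axis_angle_concentration`` (0 = isotropic).  Lifetimes are exponential
    with mean ``lifetime_mean_s``.
    """

    speed_mean_by_zone: tuple[float, ...] = field(default_factory=_default_speed_means)
    speed_sd: float = 0.1
    axis_angle_concentration: float = 1.0
    lifetime_mean_s: float = 8.0
    birth_rate_per_s: float = 5.5
    birth_density_by_zone: tuple[float, ...] = field(
        default_factory=_default_birth_weights
    )

    def __post_init__(self) -> None:
        if len(self.speed_mean_by_zone) != len(self.birth_density_by_zone):
            raise ValueError("speed means and birth weights must have equal length")
        if any(m < 0 for m in self.speed_mean_by_zone):
            raise ValueError("zone speed means must be non-negative")
        if any(m > 1 for m in self.speed_mean_by_zone):
            warnings.warn(
                "zone speed means above 1 µm/s will be clipped", stacklevel=2
            )
        if self.speed_sd < 0:
            raise ValueError("speed_sd must be non-negative")
        if self.axis_angle_concentration < 0:
            raise ValueError("axis_angle_concentration must be non-negative")
        if self.lifetime_mean_s <= 0:
            raise ValueError("lifetime_mean_s must be positive")
        if self.birth_rate_per_s < 0:
            raise ValueError("birth_rate_per_s must be non-negative")
        if any(w < 0 for w in self.birth_density_by_zone):
            raise ValueError("birth weights must be non-negative")

    @property
    def n_zones(self) -> int:
        return len(self.speed_mean_by_zone)

    @property
    def zone_weights(self) -> np.ndarray:
        """Birth weights normalised to sum to 1."""
        w = np.asarray(self.birth_density_by_zone, dtype=float)
        total = w.sum()
        if total == 0:
            raise ValueError("birth_density_by_zone weights are all zero")
        return w / total

    def mixture_mean_speed(self) -> float:
        """Analytic mean of the (unclipped) trajectory-speed mixture."""
        return float(self.zone_weights @ np.asarray(self.speed_mean_by_zone))


@dataclass(frozen=True)
class SimulationConfig:
    """Complete, self-consistent configuration of one simulated cell."""

    phase: str = "metaphase"
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    optics: OpticsModel = field(default_factory=OpticsModel)
    comet: CometModel = field(default_factory=CometModel)
    geometry: GeometryModel = field(default_factory=GeometryModel)
    motion: MotionModel = field(default_factory=MotionModel)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


class SpindleGeometryTrack:
    """Per-frame centrosome pair positions plus the full rigid spindle pose.

    ``centrosome1_um``/``centrosome2_um`` are ``(n_frames, 3)`` xyz arrays in
    µm.  ``rotations`` (``(n_frames, 3, 3)``) and ``midpoints_um`` give the
    rigid map from the spindle's own frame to the lab frame,
    ``p_lab = R @ p_spindle + m``; simulated comets are rigid with the spindle
    and use this pose.
    """

    def __init__(
        self,
        phase: str,
        centrosome1_um: np.ndarray,
        centrosome2_um: np.ndarray,
        rotations: np.ndarray | None = None,
        midpoints_um: np.ndarray | None = None,
    ) -> None:
        c1 = np.asarray(centrosome1_um, dtype=float)
        c2 = np.asarray(centrosome2_um, dtype=float)
        if c1.shape != c2.shape or c1.ndim != 2 or c1.shape[1] != 3:
            raise ValueError("centrosome tracks must be (n_frames, 3) arrays")
        d = np.linalg.norm(c2 - c1, axis=1)
        if np.any(d <= 0):
            raise ValueError("intercentrosomal distance must stay positive")
        self.phase = phase
        self.centrosome1_um = c1
        self.centrosome2_um = c2
        self.rotations = rotations
        self.midpoints_um = (
            midpoints_um if midpoints_um is not None else 0.5 * (c1 + c2)
        )

    @property
    def n_frames(self) -> int:
        return self.centrosome1_um.shape[0]

    @property
    def d_um(self) -> np.ndarray:
        """Per-frame intercentrosomal distance, µm."""
        return np.linalg.norm(self.centrosome2_um - self.centrosome1_um, axis=1)


@dataclass
class GroundTruthTrajectory:
    """One simulated comet trajectory: consecutive per-frame 3D positions."""

    id: int
    start_frame: int
    positions_um: np.ndarray  # (n_points, 3) xyz, µm
    true_mean_speed: float  # path length / elapsed time, µm/s
    zone_true: int = -1
    pole_true: int = 0

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.positions_um.ndim != 2 or self.positions_um.shape[1] != 3:
            raise ValueError("positions_um must be an (n, 3) array")
        if len(self.positions_um) < 2:
            raise ValueError("a trajectory needs at least 2 positions")
        if self.start_frame < 0:
            raise ValueError("start_frame must be >= 0")

    @property
    def n_points(self) -> int:
        return len(self.positions_um)

    @property
    def frames(self) -> np.ndarray:
        return self.start_frame + np.arange(self.n_points)
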