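"""Rigid registration of tracks into the canonical spindle frame.

The spindle, not the lab, is the natural reference frame during division:
the whole apparatus translates and rotates while comets move within it.
Registration maps each frame by the rigid transform that puts the centrosome
midpoint at the origin and the pole-1 → pole-2 direction on +x, so after
registration the poles sit at ``(∓d(t)/2, 0, 0)`` at every frame.

Two centrosomes leave the roll angle about the spindle axis undetermined;
it is fixed by choosing, at each frame, the roll that minimises the rotation
relative to the previous registered frame (first frame: the minimal rotation
from the lab frame).  This keeps registered trajectories temporally smooth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .models import SpindleGeometryTrack
from .rotations import axis_angle_matrix, minimal_rotation
from .tracking import Track, compute_mean_travel_speed

__all__ = [
    "RigidTransform",
    "canonical_transform",
    "series_transforms",
    "register_series",
    "merge_cells",
]

_EX = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map ``p -> R @ p + t`` (µm); composable and invertible."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or np.linalg.det(r) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", np.asarray(self.translation, float))

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        p = np.asarray(points_um, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def canonical_transform(c1_um: np.ndarray, c2_um: np.ndarray) -> RigidTransform:
    """Rigid map placing the midpoint at the origin and c1→c2 along +x.

    The rotation is the minimal (smallest-angle) rotation taking the
    intercentrosomal direction onto +x; c1 maps to ``(-d/2, 0, 0)`` and c2 to
    ``(+d/2, 0, 0)``.  An antiparallel axis uses a deterministic 180-degree
    rotation about +z.
    """
    c1 = np.asarray(c1_um, dtype=float)
    c2 = np.asarray(c2_um, dtype=float)
    if np.linalg.norm(c2 - c1) < 1e-12:
        raise ValueError("centrosomes are coincident; the spindle axis is undefined")
    rot = minimal_rotation(c2 - c1, _EX)
    mid = 0.5 * (c1 + c2)
    return RigidTransform(rot, -rot @ mid)


def _roll_adjustment(current: np.ndarray, previous: np.ndarray) -> float:
    """Roll angle about +x minimising the rotation from ``previous``.

    Maximises ``trace(Rx(phi) @ current @ previous.T)`` in closed form.
    """
    m = current @ previous.T
    return float(np.arctan2(m[2, 1] - m[1, 2], m[1, 1] + m[2, 2]))


def series_transforms(geometry: SpindleGeometryTrack) -> list[RigidTransform]:
    """Per-frame canonical transforms with temporally smooth roll."""
    transforms: list[RigidTransform] = []
    prev_rot = np.eye(3)
    for f in range(geometry.n_frames):
        base = canonical_transform(
            geometry.centrosome1_um[f], geometry.centrosome2_um[f]
        )
        phi = _roll_adjustment(base.rotation, prev_rot)
        rot = axis_angle_matrix(_EX, phi) @ base.rotation
        mid = 0.5 * (geometry.centrosome1_um[f] + geometry.centrosome2_um[f])
        tf = RigidTransform(rot, -rot @ mid)
        transforms.append(tf)
        prev_rot = rot
    return transforms


def register_series(
    tracks: list[Track],
    geometry: SpindleGeometryTrack,
    interval_s: float = 0.755,
) -> tuple[list[Track], SpindleGeometryTrack, list[RigidTransform]]:
    """Register tracks into the canonical spindle frame, frame by frame.

    Every track position at frame ``t`` is mapped by that frame's transform;
    each frame's map is an isometry, so same-frame distances and per-step
    lengths are preserved exactly.  Returns the registered tracks, the
    (now static-axis) registered geometry, and the per-frame transforms.
    """
    transforms = series_transforms(geometry)
    n = geometry.n_frames
    registered: list[Track] = []
    for t in tracks:
        if t.start_frame < 0 or t.start_frame + t.n_points > n:
            missing = [f for f in t.frames if f < 0 or f >= n]
            raise ValueError(
                f"track {t.id} spans frames without centrosome data: {missing}"
            )
        new_pos = np.array(
            [transforms[f].apply(p) for f, p in zip(t.frames, t.positions_um)]
        )
        rt = Track(
            id=t.id,
            start_frame=t.start_frame,
            positions_um=new_pos,
            cell_id=t.cell_id,
        )
        rt.mean_travel_speed = compute_mean_travel_speed(rt, interval_s)
        registered.append(rt)
    reg_c1 = np.array(
        [transforms[f].apply(geometry.centrosome1_um[f]) for f in range(n)]
    )
    reg_c2 = np.array(
        [transforms[f].apply(geometry.centrosome2_um[f]) for f in range(n)]
    )
    reg_geometry = SpindleGeometryTrack(geometry.phase, reg_c1, reg_c2)
    return registered, reg_geometry, transforms


def merge_cells(
    cells: list[tuple[str, list[Track], SpindleGeometryTrack]],
    allow_mixed_phases: bool = False,
    normalize_by_d: bool = False,
) -> tuple[list[Track], float]:
    """Pool registered cells into one trajectory set in the common frame.

    Each entry is ``(cell_id, registered_tracks, registered_geometry)``.
    Cell identity is retained on every track.  With ``normalize_by_d`` each
    cell's coordinates are divided by its mean intercentrosomal distance
    (off by default).  Returns the merged tracks and the pooled mean d
    (1.0 when normalising).
    """
    if not cells:
        return [], float("nan")
    phases = {geom.phase for _, _, geom in cells}
    if len(phases) > 1 and not allow_mixed_phases:
        raise ValueError(
            f"refusing to merge cells from different phases {sorted(phases)}; "
            "pass allow_mixed_phases=True to override"
        )
    merged: list[Track] = []
    next_id = 0
    d_values = []
    for cell_id, tracks, geom in cells:
        d_mean = float(np.mean(geom.d_um))
        d_values.append(1.0 if normalize_by_d else d_mean)
        scale = 1.0 / d_mean if normalize_by_d else 1.0
        for t in tracks:
            nt = copy.deepcopy(t)
            nt.id = next_id
            nt.cell_id = cell_id
            nt.positions_um = nt.positions_um * scale
            nt.mean_travel_speed = t.mean_travel_speed * scale
            merged.append(nt)
            next_id += 1
    return merged, float(np.mean(d_values))
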