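"""Small rotation helpers shared by the simulator and the registration stage."""

from __future__ import annotations

import numpy as np

__all__ = ["axis_angle_matrix", "minimal_rotation", "unit"]


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalise the zero vector")
    return v / n


def axis_angle_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``angle_rad`` (Rodrigues' formula)."""
    a = unit(axis)
    k = np.array(
        [[0.0, -a[2], a[1]], [a[2], 0.0, -a[0]], [-a[1], a[0], 0.0]]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1.0 - np.cos(angle_rad)) * (k @ k)


def minimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Smallest-angle rotation taking unit vector ``source`` onto ``target``.

    The rotation axis is the cross product of the two directions.  When they
    are antiparallel the rotation is underdetermined; a 180-degree rotation
    about an axis perpendicular to ``source`` is chosen deterministically
    (+z where possible, +y when the directions lie along z).
    """
    s = unit(source)
    t = unit(target)
    c = float(np.dot(s, t))
    axis = np.cross(s, t)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: pick a perpendicular axis deterministically
        perp = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(perp, s)) > 1.0 - 1e-9:
            perp = np.array([0.0, 1.0, 0.0])
        perp = unit(perp - np.dot(perp, s) * s)
        return axis_angle_matrix(perp, np.pi)
    angle = np.arctan2(norm, c)
    return axis_angle_matrix(axis / norm, angle)
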