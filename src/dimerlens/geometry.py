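"""Minimum-image geometry primitives for orthorhombic periodic boxes.

All coordinates are in nm, all angles in degrees. Boxes are orthorhombic
``(Lx, Ly, Lz)``; the minimum-image convention wraps each Cartesian
component independently, which is exact for such boxes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "min_image",
    "pairwise_min_distance",
    "dihedral",
    "wrap_coordinates",
]


def min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Parameters
    ----------
    delta
        Array of displacement vectors, shape ``(..., 3)``.
    box
        Orthorhombic box lengths ``(Lx, Ly, Lz)``.
    """
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def wrap_coordinates(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary cell ``[0, L)`` per axis."""
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float)
    return coords - box * np.floor(coords / box)


def pairwise_min_distance(
    coords_a: np.ndarray, coords_b: np.ndarray, box: np.ndarray
) -> float:
    """Minimum over all (a, b) pairs of the minimum-image distance.

    ``coords_a`` has shape ``(na, 3)`` and ``coords_b`` ``(nb, 3)``; the
    scan is exhaustive (no cell lists), which is exact and fast enough for
    the bead counts handled here.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty coordinate set in pairwise_min_distance")
    d = min_image(a[:, None, :] - b[None, :, :], box)
    return float(np.sqrt((d * d).sum(axis=-1)).min())


def dihedral(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    p4: np.ndarray,
    box: np.ndarray | None = None,
) -> float:
    """Signed four-point dihedral angle in degrees, range (-180, 180].

    The angle is measured between the half-plane containing ``p1`` and the
    half-plane containing ``p4``, both hinged on the ``p2 -> p3`` axis, with
    a right-handed sign about that axis: the canonical staircase
    ``(0,0,0), (1,0,0), (1,1,0), (1,1,1)`` gives +90 deg.

    If ``box`` is given, every bond vector is reduced by the minimum-image
    convention so that molecules split across periodic boundaries are
    handled correctly.

    Returns NaN when either bounding plane is degenerate (collinear points).
    """
    b1 = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    b2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    b3 = np.asarray(p4, dtype=float) - np.asarray(p3, dtype=float)
    if box is not None:
        b1 = min_image(b1, box)
        b2 = min_image(b2, box)
        b3 = min_image(b3, box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 == 0.0 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        return float("nan")
    y = np.dot(np.cross(n1, n2), b2 / norm_b2)
    x = np.dot(n1, n2)
    angle = float(np.degrees(np.arctan2(y, x)))
    if angle <= -180.0:
        angle += 360.0
    return angle


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about an arbitrary axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(t) * k + (1.0 - np.cos(t)) * (k @ k)
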