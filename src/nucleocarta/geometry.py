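"""Small polygon utilities shared across the pipeline.

Coordinate convention (used everywhere): pixel frame with x rightward and
y downward, pixel centres at integer coordinates. In this frame the
oriented nucleus has its hook tip on the left and its dorsal side at
smaller y (so it displays hook-up); boundaries are traversed with positive
shoelace area, which runs from the hook tip along the dorsal side first.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon


def signed_area(boundary: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon given as an (N, 2) array."""
    x, y = boundary[:, 0], boundary[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_positive_orientation(boundary: np.ndarray) -> np.ndarray:
    """Return the boundary traversed with positive shoelace area."""
    return boundary if signed_area(boundary) >= 0 else boundary[::-1].copy()


def perimeter(boundary: np.ndarray) -> float:
    d = np.roll(boundary, -1, axis=0) - boundary
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def cumulative_arc(boundary: np.ndarray) -> np.ndarray:
    """Arc length from point 0 to each point, plus the closing total.

    Returns an array of length N+1; the last entry is the perimeter.
    """
    d = np.roll(boundary, -1, axis=0) - boundary
    seg = np.sqrt((d**2).sum(axis=1))
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_closed(boundary: np.ndarray, n: int, start_arc: float = 0.0) -> np.ndarray:
    """Resample a closed boundary to ``n`` arc-length-equidistant points.

    ``start_arc`` selects where (in arc length from point 0) the first
    resampled point sits.
    """
    s = cumulative_arc(boundary)
    per = s[-1]
    closed = np.vstack([boundary, boundary[:1]])
    si = (start_arc + np.linspace(0.0, per, n, endpoint=False)) % per
    x = np.interp(si, s, closed[:, 0])
    y = np.interp(si, s, closed[:, 1])
    return np.c_[x, y]


def resample_open(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to ``n`` arc-length-equidistant points
    (endpoints preserved)."""
    d = np.diff(points, axis=0)
    seg = np.sqrt((d**2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    si = np.linspace(0.0, s[-1], n)
    return np.c_[np.interp(si, s, points[:, 0]), np.interp(si, s, points[:, 1])]


def is_simple_polygon(boundary: np.ndarray) -> bool:
    try:
        return Polygon(boundary).is_simple and Polygon(boundary).is_valid
    except Exception:
        return False


def cyclic_arc_distance(i: int, j: int, n: int) -> int:
    """Shortest cyclic index distance between boundary indices i and j."""
    d = abs(int(i) - int(j)) % n
    return min(d, n - d)


def rigid_transform(angle: float, shift: np.ndarray, mirror_y: bool = False) -> np.ndarray:
    """2x3 affine: optional y-mirror, then rotation by ``angle``, then shift."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    if mirror_y:
        rot = rot @ np.array([[1.0, 0.0], [0.0, -1.0]])
    return np.c_[rot, np.asarray(shift, dtype=float)]


def apply_affine(transform: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 2x3 affine to an (N, 2) point array."""
    return points @ transform[:, :2].T + transform[:, 2]


def invert_affine(transform: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(transform[:, :2])
    return np.c_[inv, -inv @ transform[:, 2]]
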