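"""Plane-geometry primitives shared across the pipeline.

Coordinate convention used throughout the package: a point is ``(x, y)`` in
millimetres with ``x`` = raster column and ``y`` = raster row, *y increasing
upward* (row 0 is the bottom of the slice).  Under this convention a closed
curve traversed clockwise has negative shoelace area; the package stores
curves clockwise and reports absolute areas.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (negative for clockwise, y-up)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(points: np.ndarray) -> float:
    return abs(signed_area(points))


def segment_lengths(points: np.ndarray) -> np.ndarray:
    """Lengths of the N closing segments of a closed polygon (point i -> i+1)."""
    p = np.asarray(points, dtype=float)
    return np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)


def perimeter(points: np.ndarray) -> float:
    return float(segment_lengths(points).sum())


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each vertex of a closed polygon, length N+1.

    Entry 0 is 0.0 and entry N is the full perimeter.
    """
    return np.concatenate([[0.0], np.cumsum(segment_lengths(points))])


def is_simple_polygon(points: np.ndarray) -> bool:
    p = np.asarray(points, dtype=float)
    ring = LineString(np.vstack([p, p[:1]]))
    return bool(ring.is_simple)


def resample_closed(points: np.ndarray, k: int, *, uniform_rtol: float = 0.25):
    """Resample a closed polygon to ``k`` points at equal arc-length spacing.

    Preserves orientation and the start point.  If the input already has ``k``
    vertices with chord lengths uniform to ``uniform_rtol`` (relative to the
    mean chord), the input is returned unchanged.  Arc-length resampling of a
    polygon is not a mathematical projection (chords re-cut corners), so this
    generous same-K fast path is what makes repeated resampling exactly
    idempotent; pixel-centre staircase curves need the wide tolerance.

    Returns (points_k, arc_positions) where arc_positions are the arc-length
    coordinates (along the *input* polygon) of the output points.
    """
    p = np.asarray(points, dtype=float)
    n = len(p)
    if n < 3:
        raise ValueError("need at least 3 points to resample a closed curve")
    seg = segment_lengths(p)
    total = float(seg.sum())
    if total <= 0:
        raise ValueError("degenerate curve with zero perimeter")
    if n == k:
        mean = total / n
        if np.max(np.abs(seg - mean)) <= uniform_rtol * mean:
            return p.copy(), cumulative_arclength(p)[:-1]
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(k) * (total / k)
    closed = np.vstack([p, p[:1]])
    out = np.empty((k, 2))
    out[:, 0] = np.interp(targets, cum, closed[:, 0])
    out[:, 1] = np.interp(targets, cum, closed[:, 1])
    return out, targets


def nearest_vertex_index(points: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Index of the nearest vertex of ``points`` for each query point."""
    from scipy.spatial import cKDTree

    return cKDTree(np.asarray(points, dtype=float)).query(np.asarray(queries, dtype=float))[1]


def outward_normals(points: np.ndarray) -> np.ndarray:
    """Unit outward normals at the vertices of a *clockwise* (y-up) polygon.

    The vertex normal averages the two adjacent segment normals; for a
    clockwise curve the outward segment normal of tangent t is (-t_y, t_x).
    """
    p = np.asarray(points, dtype=float)
    tang = np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)
    norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    length = np.linalg.norm(norm, axis=1)
    length[length == 0] = 1.0
    return norm / length[:, None]


def rotation_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def apply_rigid(points: np.ndarray, theta: float, translation) -> np.ndarray:
    return np.asarray(points, dtype=float) @ rotation_matrix(theta).T + np.asarray(translation, dtype=float)


def cyclic_interval_distance(positions: np.ndarray, interval, period: float) -> np.ndarray:
    """Cyclic arc distance from positions to a half-open interval [a, b).

    All quantities share the same units (arc length along a closed curve of
    the given period).  Points inside the interval have distance 0.
    """
    a, b = interval
    pos = np.mod(np.asarray(positions, dtype=float), period)
    a = a % period
    b = b % period
    if a <= b:
        inside = (pos >= a) & (pos < b)
    else:
        inside = (pos >= a) | (pos < b)
    d_a = np.minimum(np.abs(pos - a), period - np.abs(pos - a))
    d_b = np.minimum(np.abs(pos - b), period - np.abs(pos - b))
    dist = np.minimum(d_a, d_b)
    dist[inside] = 0.0
    return dist


def rasterize_labeled_polygon(points: np.ndarray, labels: np.ndarray, grid_shape) -> np.ndarray:
    """Rasterize a closed labeled outline onto an integer label grid.

    Pixels whose centres fall inside the polygon (plus the outline pixels
    themselves) are foreground; each foreground pixel takes the sub-region
    label of the nearest outline vertex.  Grid is indexed ``grid[y, x]``.
    """
    from scipy.spatial import cKDTree
    from skimage.draw import polygon as draw_polygon

    p = np.asarray(points, dtype=float)
    ny, nx = grid_shape
    rr, cc = draw_polygon(p[:, 1], p[:, 0], shape=(ny, nx))
    # outline pixels: round vertex coordinates onto the grid
    orr = np.clip(np.rint(p[:, 1]).astype(int), 0, ny - 1)
    occ = np.clip(np.rint(p[:, 0]).astype(int), 0, nx - 1)
    rr = np.concatenate([rr, orr])
    cc = np.concatenate([cc, occ])
    grid = np.zeros((ny, nx), dtype=np.int16)
    if len(rr) == 0:
        return grid
    centres = np.stack([cc, rr], axis=1).astype(float)  # (x, y)
    idx = cKDTree(p).query(centres)[1]
    grid[rr, cc] = np.asarray(labels)[idx]
    return grid
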