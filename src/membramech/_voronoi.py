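"""Periodic planar Voronoi tessellation via 3×3 image tiling.

The primary cell is tiled with its 8 periodic neighbor copies; only cells
whose seed lies in the primary image are counted.  This reproduces the
periodic tessellation exactly for orthorhombic boxes: cell areas per image
sum to the box cross-section, and the adjacency graph is the periodic one.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import QhullError, Voronoi


_OFFSETS = np.array(
    [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1) if (i, j) != (0, 0)], dtype=float
)


def _tile(points: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    images = [points] + [points + off * box_xy for off in _OFFSETS]
    return np.vstack(images)


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def periodic_voronoi(points: np.ndarray, box_xy) -> Voronoi:
    """Voronoi diagram of points tiled with their 8 periodic images.

    Degenerate seed sets (duplicates / collinear) are jittered by 1e-8 Å and
    retried once before the failure propagates.
    """
    box_xy = np.asarray(box_xy, dtype=float)
    points = np.mod(np.asarray(points, dtype=float), box_xy)
    # coincident seeds make qhull share regions silently; jitter them apart
    has_duplicates = (
        np.unique(np.round(points / 1e-7).astype(np.int64), axis=0).shape[0]
        < points.shape[0]
    )
    if not has_duplicates:
        try:
            return Voronoi(_tile(points, box_xy))
        except QhullError:
            pass
    rng = np.random.default_rng(0)
    jittered = points + rng.normal(scale=1e-6, size=points.shape)
    return Voronoi(_tile(jittered, box_xy))


def periodic_voronoi_areas(points: np.ndarray, box_xy) -> np.ndarray:
    """Area of the periodic Voronoi cell of each seed (primary image only).

    The returned areas sum to the box cross-section up to floating-point
    round-off.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 3:
        raise ValueError("periodic Voronoi needs at least 3 seeds")
    vor = periodic_voronoi(points, box_xy)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("unbounded primary Voronoi cell; box tiling failed")
        areas[i] = _polygon_area(vor.vertices[region])
    return areas


def periodic_voronoi_neighbors(points: np.ndarray, box_xy) -> set[tuple[int, int]]:
    """Neighbor pairs (i < j) of the periodic Voronoi adjacency graph."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    vor = periodic_voronoi(points, box_xy)
    pairs: set[tuple[int, int]] = set()
    for p, q in vor.ridge_points:
        if p >= n and q >= n:
            continue  # ridge entirely between image copies
        a, b = int(p % n), int(q % n)
        if a == b:
            continue  # a seed facing its own periodic image
        pairs.add((a, b) if a < b else (b, a))
    return pairs
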