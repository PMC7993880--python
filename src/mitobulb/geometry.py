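"""Convex-hull Feret diameters shared by morphometry and STORM shape analysis.

The minimum Feret diameter (width between parallel supporting lines) of a
convex polygon is attained with one line flush against a hull edge, so the
exact minimum is found by iterating over hull edges; the maximum Feret
diameter is the hull diameter (max pairwise vertex distance).  Hull vertex
counts are small, so the O(V^2) scan is exact and fast.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = ["convex_hull_vertices", "feret_diameters", "CollinearPointsError"]


class CollinearPointsError(ValueError):
    """Point set has no 2D extent (fewer than 3 points, or all collinear)."""


def convex_hull_vertices(points: np.ndarray) -> np.ndarray:
    """Return hull vertices (counter-clockwise) of an (n, 2) point array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        raise CollinearPointsError("need >= 3 points for a 2D hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise CollinearPointsError("degenerate (collinear) point set") from exc
    return pts[hull.vertices]


def feret_diameters(points: np.ndarray) -> tuple[float, float]:
    """Exact (min_feret, max_feret) of the convex hull of ``points``.

    max_feret is the largest pairwise distance between hull vertices;
    min_feret is the smallest width over hull-edge directions.
    """
    v = convex_hull_vertices(points)
    diff = v[:, None, :] - v[None, :, :]
    d_max = float(np.sqrt((diff**2).sum(-1)).max())

    n = len(v)
    edges = np.roll(v, -1, axis=0) - v
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    edges, base = edges[keep] / lengths[keep, None], v[keep]
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1)
    # width for each edge direction: max |(v - base) . n|
    rel = v[None, :, :] - base[:, None, :]
    widths = np.abs(np.einsum("eij,ej->ei", rel, normals)).max(axis=1)
    d_min = float(widths.min())
    if d_min <= 0:
        raise CollinearPointsError("degenerate (collinear) point set")
    return d_min, d_max
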