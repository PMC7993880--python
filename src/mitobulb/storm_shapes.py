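"""STORM localization filtering, nucleoid clustering, and shape metrics.

Localization lists are filtered by local density (keep a point iff at least
``min_count`` points, itself included, fall within ``radius_nm`` in XY — a
single pass on the original set), grouped into nucleoids by deterministic
density-based clustering, and measured per cluster: min/max XY Feret
diameters, semi-diameter (d_min + d_max)/4, and ellipticity d_max/d_min.

Two diameter estimators are provided.  "feret" takes rotating-calipers Feret
diameters of the convex hull of the points — the natural reading of a
diameter measurement, but biased upward by localization error, whose jitter
pushes hull vertices outward.  "moment" assumes uniformly labeled
ellipsoidal nucleoids observed with isotropic Gaussian localization error:
the principal variances of such a cloud are (axis/2)^2/4 + sigma_loc^2, so
subtracting the known precision variance and converting back
(d = 4*sqrt(lambda - sigma^2)) deconvolves the localization error — the
standard size correction in single-molecule cluster analysis.  Z is ignored
for shape metrics but retained in I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import CollinearPointsError, feret_diameters

__all__ = [
    "NucleoidShape",
    "ShapeSummary",
    "density_filter",
    "cluster_localizations",
    "shape_metrics",
    "measure_clusters",
]

LOC_COLUMNS = ["id", "x_nm", "y_nm", "z_nm", "photons", "frame"]


@dataclass
class NucleoidShape:
    cluster_id: int
    n_locs: int
    d_min: float  # nm
    d_max: float  # nm
    semi_diameter: float  # nm
    ellipticity: float  # >= 1
    border_flag: bool = False


@dataclass
class ShapeSummary:
    shapes: list
    mean_semi_diameter: float
    sd_semi_diameter: float
    mean_ellipticity: float
    sd_ellipticity: float
    n_clusters: int
    skipped: list  # (cluster_id, reason)


def _xy(locs: pd.DataFrame) -> np.ndarray:
    return locs[["x_nm", "y_nm"]].to_numpy(dtype=float)


def density_filter(locs: pd.DataFrame, radius_nm: float = 70.0,
                   min_count: int = 10) -> pd.DataFrame:
    """Keep localizations with >= min_count neighbors (self included) within
    radius_nm in XY.  Single pass on the original set; not iterated."""
    if radius_nm <= 0 or min_count < 1:
        raise ValueError("radius must be > 0 and min_count >= 1")
    if locs.empty:
        return locs.copy()
    pts = _xy(locs)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, radius_nm, return_length=True)
    return locs.loc[counts >= min_count].reset_index(drop=True)


def cluster_localizations(locs: pd.DataFrame, eps_nm: float = 70.0,
                          min_pts: int = 10) -> np.ndarray:
    """Deterministic density-based (DBSCAN-style) clustering on XY.

    Core points have >= min_pts neighbors (self included) within eps_nm;
    clusters are the connected components of core points under the
    within-eps relation, numbered 1..K by their lowest-index core point.
    A non-core (border) point within eps of a core point joins the cluster
    of its nearest core point (ties broken by lowest index); remaining
    points are noise, labeled 0.  The rule depends only on coordinates and
    row order, so results are reproducible for a given input table.
    """
    if eps_nm <= 0 or min_pts < 1:
        raise ValueError("eps must be > 0 and min_pts >= 1")
    n = len(locs)
    labels = np.zeros(n, dtype=int)
    if n == 0:
        return labels
    pts = _xy(locs)
    tree = cKDTree(pts)
    core = tree.query_ball_point(pts, eps_nm, return_length=True) >= min_pts
    core_idx = np.flatnonzero(core)
    if len(core_idx) == 0:
        return labels

    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    core_tree = cKDTree(pts[core_idx])
    pairs = core_tree.query_pairs(eps_nm, output_type="ndarray")
    m = len(core_idx)
    graph = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                       shape=(m, m))
    _, comp = connected_components(graph, directed=False)
    # renumber components 1..K by lowest core index (scan order)
    order = {}
    for c in comp:
        if c not in order:
            order[c] = len(order) + 1
    labels[core_idx] = [order[c] for c in comp]

    border_idx = np.flatnonzero(~core)
    if len(border_idx):
        hits = core_tree.query_ball_point(pts[border_idx], eps_nm)
        for b, hit in zip(border_idx, hits):
            if not hit:
                continue
            cand = core_idx[hit]
            d2 = ((pts[cand] - pts[b]) ** 2).sum(axis=1)
            best = cand[np.lexsort((cand, d2))[0]]
            labels[b] = labels[best]
    return labels


def shape_metrics(points_nm: np.ndarray, cluster_id: int = 1,
                  method: str = "feret",
                  localization_precision: float = 0.0,
                  semi_mode: str = "mean",
                  field_bounds: tuple | None = None,
                  border_margin_nm: float = 70.0) -> NucleoidShape:
    """Shape of one cluster from its XY points.

    method "feret": rotating-calipers min/max Feret of the convex hull.
    method "moment": precision-corrected moment diameters, d = 4*sqrt(max(
    lambda_i - sigma_loc^2, 0)) from the eigenvalues of the XY covariance.
    semi_mode "mean" gives semi_diameter = (d_min + d_max)/4; "equivalent"
    gives the equivalent-circle radius sqrt(d_min * d_max)/2.  A cluster with
    fewer than 3 points or no 2D extent raises CollinearPointsError.
    """
    pts = np.asarray(points_nm, dtype=float)[:, :2]
    if method == "feret":
        d_min, d_max = feret_diameters(pts)
    elif method == "moment":
        if len(pts) < 3:
            raise CollinearPointsError("need >= 3 points")
        lam = np.linalg.eigvalsh(np.cov(pts.T))
        lam = lam - localization_precision**2
        if lam[0] <= 0:
            raise CollinearPointsError("no resolvable extent after "
                                       "precision correction")
        d_min, d_max = 4 * np.sqrt(lam[0]), 4 * np.sqrt(lam[1])
    else:
        raise ValueError("method must be 'feret' or 'moment'")

    if semi_mode == "mean":
        semi = (d_min + d_max) / 4
    elif semi_mode == "equivalent":
        semi = np.sqrt(d_min * d_max) / 2
    else:
        raise ValueError("semi_mode must be 'mean' or 'equivalent'")

    border = False
    if field_bounds is not None:
        x0, y0, x1, y1 = field_bounds
        border = bool((pts[:, 0] < x0 + border_margin_nm).any()
                      or (pts[:, 0] > x1 - border_margin_nm).any()
                      or (pts[:, 1] < y0 + border_margin_nm).any()
                      or (pts[:, 1] > y1 - border_margin_nm).any())
    return NucleoidShape(cluster_id=cluster_id, n_locs=len(pts),
                         d_min=float(d_min), d_max=float(d_max),
                         semi_diameter=float(semi),
                         ellipticity=float(d_max / d_min), border_flag=border)


def measure_clusters(locs: pd.DataFrame, labels: np.ndarray,
                     method: str = "feret",
                     localization_precision: float = 0.0,
                     semi_mode: str = "mean",
                     field_bounds: tuple | None = None,
                     border_margin_nm: float = 70.0) -> ShapeSummary:
    """Shape metrics for every cluster plus the population mean +/- SD.

    Clusters touching the field border (within ``border_margin_nm`` of
    ``field_bounds``) are measured but excluded from the population summary;
    degenerate clusters are skipped with a reason.
    """
    shapes, skipped = [], []
    for cid in sorted(set(labels) - {0}):
        pts = _xy(locs[labels == cid])
        try:
            shapes.append(shape_metrics(
                pts, cid, method=method,
                localization_precision=localization_precision,
                semi_mode=semi_mode, field_bounds=field_bounds,
                border_margin_nm=border_margin_nm))
        except CollinearPointsError as exc:
            skipped.append((int(cid), str(exc)))
    pop = [s for s in shapes if not s.border_flag]
    semi = np.array([s.semi_diameter for s in pop])
    ell = np.array([s.ellipticity for s in pop])
    return ShapeSummary(
        shapes=shapes,
        mean_semi_diameter=float(semi.mean()) if len(pop) else float("nan"),
        sd_semi_diameter=float(semi.std(ddof=1)) if len(pop) > 1 else float("nan"),
        mean_ellipticity=float(ell.mean()) if len(pop) else float("nan"),
        sd_ellipticity=float(ell.std(ddof=1)) if len(pop) > 1 else float("nan"),
        n_clusters=len(pop), skipped=skipped)
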