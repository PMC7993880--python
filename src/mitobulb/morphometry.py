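"""Organelle segmentation and mito-bulb incidence scoring.

The pipeline mirrors an interactive-watershed particle analysis: optional 3x3
mean smoothing, seeded watershed on the inverted matrix-reporter intensity
with h-maxima seeds restricted to thresholded foreground, per-label particle
features (area, perimeter, circularity, Feret diameters), and a threshold
sweep counting near-circular particles above each cross-sectional area
cutoff, normalized per cell.  A small tracker follows the minor diameter of
one bulb through a time-lapse by nearest-centroid association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label as cc_label, regionprops
from skimage.morphology import h_maxima
from skimage.segmentation import relabel_sequential, watershed

from .geometry import CollinearPointsError, feret_diameters

__all__ = [
    "LabelImage",
    "ParticleFeatures",
    "BulbCountReport",
    "TrackPoint",
    "smooth",
    "segment_organelles",
    "segment_noisy",
    "measure_particles",
    "count_mitobulbs",
    "aggregate_reports",
    "track_bulb_diameter",
]

#: relative circularity tolerance allowed before clamping to 1
CIRCULARITY_TOL = 0.05


@dataclass
class LabelImage:
    labels: np.ndarray  # 2D int, 0 = background
    pixel_size: float  # um/pixel

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.pixel_size <= 0:
            raise ValueError("labels must be 2D and pixel_size > 0")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


@dataclass
class ParticleFeatures:
    label_id: int
    area: float  # um^2
    perimeter: float  # um
    circularity: float  # 4*pi*A/P^2, clamped to <= 1
    min_feret: float  # um
    max_feret: float  # um
    centroid: tuple[float, float]  # (x, y) um


@dataclass
class BulbCountReport:
    """Mito-bulb counts per area threshold, normalized per cell."""

    area_thresholds: list[float]
    counts: list[int]
    bulbs_per_cell: list[float]
    n_cells: int
    n_images: int = 1
    mean: list[float] | None = None  # across-image mean of bulbs/cell
    sd: list[float] | None = None


def smooth(image: np.ndarray) -> np.ndarray:
    """3x3 uniform mean filter with reflected borders, applied once."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D raster")
    return ndimage.uniform_filter(img, size=3, mode="reflect")


def segment_organelles(image: np.ndarray, pixel_size: float,
                       h: float | None = None,
                       intensity_threshold: float | None = None) -> LabelImage:
    """Seeded watershed segmentation of the matrix-reporter channel.

    Foreground is ``image >= intensity_threshold`` (Otsu by default); seeds
    are h-maxima regions of the image within the foreground, with the seed
    dynamic ``h`` defaulting to 10% of the foreground dynamic range.  The
    watershed floods the inverted intensity restricted to the foreground, so
    the labels partition the foreground exactly; any foreground component
    left without a seed becomes its own label.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D raster")
    if intensity_threshold is None:
        if np.ptp(img) == 0:
            return LabelImage(np.zeros(img.shape, np.int32), pixel_size)
        intensity_threshold = float(threshold_otsu(img))
    fg = img >= intensity_threshold
    if not fg.any():
        return LabelImage(np.zeros(img.shape, np.int32), pixel_size)
    if h is None:
        h = 0.1 * float(img[fg].max() - intensity_threshold)
    if h <= 0:
        h = 1e-6 * max(1.0, float(np.ptp(img)))

    seeds = h_maxima(img, h) & fg
    markers = cc_label(seeds, connectivity=2)
    labels = watershed(-img, markers=markers, mask=fg)

    # orphan foreground components (no h-maximum inside) get fresh labels
    orphan = fg & (labels == 0)
    if orphan.any():
        extra = cc_label(orphan, connectivity=2)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    labels, _, _ = relabel_sequential(labels)
    return LabelImage(labels.astype(np.int32), pixel_size)


def segment_noisy(image: np.ndarray, pixel_size: float,
                  h_fraction: float = 0.4) -> LabelImage:
    """Robust recipe for shot-noise-limited images of intensity-flat,
    spatially separated organelles: 3x3 mean smoothing, Otsu threshold, and
    a watershed seed dynamic of ``h_fraction`` of the foreground dynamic
    range so noise maxima cannot seed splits.  This plays the role the
    interactive per-image tuning plays in manual watershed analysis; for
    clean or high-contrast data use :func:`segment_organelles` directly.
    """
    img = smooth(image)
    if np.ptp(img) == 0:
        return LabelImage(np.zeros(img.shape, np.int32), pixel_size)
    thr = float(threshold_otsu(img))
    fg = img >= thr
    if not fg.any():
        return LabelImage(np.zeros(img.shape, np.int32), pixel_size)
    h = h_fraction * float(img[fg].max() - thr)
    return segment_organelles(img, pixel_size, h=h, intensity_threshold=thr)


def _outer_contour(mask: np.ndarray) -> np.ndarray:
    """Longest 0.5-level contour of a padded binary mask, in pixel coords."""
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    contour = max(contours, key=len)
    return contour - 1.0  # undo padding; (row, col)


def measure_particles(label_image: LabelImage) -> list[ParticleFeatures]:
    """Per-label area, perimeter, circularity and Feret diameters.

    Perimeter convention: Crofton formula with 4 directions, which is
    asymptotically unbiased for smooth convex outlines, so circularity of
    rasterized disks lands near 1 (naive boundary-polygon length
    overestimates smooth perimeters by ~5% at any radius).  Feret diameters
    come from rotating calipers on the convex hull of the sub-pixel
    0.5-level outer contour.
    """
    ps = label_image.pixel_size
    out: list[ParticleFeatures] = []
    for rp in regionprops(label_image.labels):
        mask = np.zeros(label_image.labels.shape, bool)
        sl = rp.slice
        mask[sl] = label_image.labels[sl] == rp.label
        contour = _outer_contour(mask[sl])
        perim = float(rp.perimeter_crofton) * ps
        area = float(rp.area) * ps * ps
        circ_raw = 4 * np.pi * area / perim**2 if perim > 0 else 0.0
        circ = min(circ_raw, 1.0) if circ_raw <= 1 + CIRCULARITY_TOL else circ_raw
        pts = contour[:, ::-1]  # (x=col, y=row)
        try:
            dmin, dmax = feret_diameters(pts)
        except CollinearPointsError:
            dmin = dmax = 0.0
        cy, cx = rp.centroid
        out.append(ParticleFeatures(
            label_id=int(rp.label), area=area, perimeter=perim,
            circularity=float(circ), min_feret=dmin * ps, max_feret=dmax * ps,
            centroid=(float(cx) * ps, float(cy) * ps)))
    return out


def count_mitobulbs(features: list[ParticleFeatures],
                    area_thresholds: list[float],
                    n_cells: int,
                    circularity_min: float = 0.8) -> BulbCountReport:
    """Count near-circular particles above each area threshold, per cell."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    thresholds = sorted(area_thresholds)
    counts, per_cell = [], []
    for t in thresholds:
        c = sum(1 for f in features
                if f.area > t and f.circularity >= circularity_min)
        counts.append(c)
        per_cell.append(c / n_cells)
    return BulbCountReport(area_thresholds=list(thresholds), counts=counts,
                           bulbs_per_cell=per_cell, n_cells=n_cells)


def aggregate_reports(reports: list[BulbCountReport]) -> BulbCountReport:
    """Across-image mean +/- SD of bulbs/cell at shared thresholds."""
    if not reports:
        raise ValueError("no reports to aggregate")
    thr = reports[0].area_thresholds
    if any(r.area_thresholds != thr for r in reports):
        raise ValueError("reports use different threshold lists")
    per = np.array([r.bulbs_per_cell for r in reports], dtype=float)
    total = [int(sum(r.counts[i] for r in reports)) for i in range(len(thr))]
    n_cells = sum(r.n_cells for r in reports)
    return BulbCountReport(
        area_thresholds=list(thr), counts=total,
        bulbs_per_cell=[t / n_cells for t in total], n_cells=n_cells,
        n_images=len(reports), mean=per.mean(axis=0).tolist(),
        sd=per.std(axis=0, ddof=1).tolist() if len(reports) > 1 else None)


@dataclass
class TrackPoint:
    frame: int
    min_diameter: float | None  # um; None when association was lost
    centroid: tuple[float, float] | None
    status: str  # "ok" | "gap" | "lost"


def track_bulb_diameter(timelapse: list[np.ndarray], initial_roi,
                        pixel_size: float, gate_um: float = 1.0,
                        max_gap: int = 3,
                        segment_kwargs: dict | None = None) -> list[TrackPoint]:
    """Follow one bulb's minor (min-Feret) diameter through a time-lapse.

    ``initial_roi`` is an (x0, y0, x1, y1) box in um containing the bulb in
    frame 0.  Each frame is segmented independently; the tracked particle is
    associated to the previous centroid by nearest neighbor within
    ``gate_um``.  After more than ``max_gap`` consecutive misses the track
    terminates with status "lost".
    """
    if len(timelapse) < 2:
        raise ValueError("need at least 2 frames")
    kw = segment_kwargs or {}
    x0, y0, x1, y1 = initial_roi
    roi_center = ((x0 + x1) / 2, (y0 + y1) / 2)

    track: list[TrackPoint] = []
    prev = None
    misses = 0
    for i, frame in enumerate(timelapse):
        feats = measure_particles(segment_organelles(frame, pixel_size, **kw))
        if i == 0:
            inside = [f for f in feats
                      if x0 <= f.centroid[0] <= x1 and y0 <= f.centroid[1] <= y1]
            if not inside:
                raise ValueError("initial ROI contains no segmented particle")
            best = min(inside, key=lambda f: (f.centroid[0] - roi_center[0])**2
                       + (f.centroid[1] - roi_center[1])**2)
        else:
            cand = [(f, np.hypot(f.centroid[0] - prev[0], f.centroid[1] - prev[1]))
                    for f in feats]
            cand = [(f, d) for f, d in cand if d <= gate_um]
            best = min(cand, key=lambda fd: fd[1])[0] if cand else None
        if best is None:
            misses += 1
            status = "lost" if misses > max_gap else "gap"
            track.append(TrackPoint(i, None, None, status))
            if status == "lost":
                break
        else:
            misses = 0
            prev = best.centroid
            track.append(TrackPoint(i, best.min_feret, best.centroid, "ok"))
    return track
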