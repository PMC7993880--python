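"""Ground-truthed synthetic scenes, rendered multi-channel images, and
single-molecule localization lists.

The generator emulates the statistical structure the downstream analysis
assumes: cells containing tubular mitochondria (constant-width smooth curves,
0.4-0.5 um diameter, singly spaced nucleoids along the midline) alongside
swollen spheroidal "mito-bulbs" (ellipses with minor diameter >= 1.2 um
holding >= 3 discrete nucleoids in one matrix space).  Each organelle carries
its own membrane-potential scaling (TMRM factor) and oxidation ratio, so the
ratiometric pipelines can be validated against known per-organelle
physiology.  Rendering applies a Gaussian PSF to extended structures, draws
nucleoids as sub-diffraction Gaussian spots, then adds Poisson shot noise on
(signal + background) followed by Gaussian read noise -- the standard
sCMOS/EMCCD forward model.  Intensity units are photons.

Determinism: every public entry point takes a seed; child generators are
derived from a single root ``numpy.random.default_rng`` per call, so identical
(params, seed) give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely import affinity
from shapely.geometry import LineString, Point, Polygon, box

__all__ = [
    "SceneParams",
    "StormParams",
    "Organelle",
    "Nucleoid",
    "GroundTruthScene",
    "PlacementError",
    "generate_scene",
    "render_image",
    "generate_localizations",
    "CHANNELS",
]

CHANNELS = ("egfp", "tmrm", "dna", "edu", "rogfp405", "rogfp488")

# margin kept between organelles / the cell boundary, and between nucleoids
_CLEARANCE_UM = 0.2
_NUCLEOID_MARGIN_UM = 0.12
_NUCLEOID_MIN_SEP_UM = 0.25


class PlacementError(RuntimeError):
    """Organelles could not be packed disjointly within their cell."""


@dataclass(frozen=True)
class SceneParams:
    """Geometry, physiology and optics of a synthetic scene.

    Lengths are um, intensities photons.  ``tmrm_factor_*`` scales the TMRM
    channel relative to the matrix (EGFP) channel per organelle class;
    ``ox_ratio_*`` is the oxidized:reduced roGFP2 excitation ratio.
    """

    n_cells: int = 1
    image_size: int = 512
    pixel_size: float = 0.06
    tubules_per_cell: int = 5
    tubule_diameter: tuple[float, float] = (0.4, 0.5)
    tubule_length: tuple[float, float] = (2.0, 5.0)
    bulbs_per_cell: int = 3
    bulb_min_diameter: tuple[float, float] = (1.2, 5.0)
    bulb_axis_ratio: tuple[float, float] = (1.0, 1.8)
    nucleoid_spacing_tubule: float = 1.0
    nucleoids_per_bulb: tuple[int, int] = (3, 6)
    edu_probability: float = 0.4
    edu_probability_clustered: float | None = None  # None -> same as edu_probability
    tmrm_factor_tubular: float = 1.0
    tmrm_factor_bulb: float = 0.8
    ox_ratio_tubular: float = 1.0
    ox_ratio_bulb: float = 2.0
    psf_sigma: float = 0.12
    background_level: float = 5.0
    read_noise_sd: float = 2.0
    egfp_density: float = 120.0  # photons/pixel inside the matrix
    nucleoid_peak_photons: float = 400.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1 or self.image_size < 16:
            raise ValueError("n_cells >= 1 and image_size >= 16 required")
        if self.pixel_size <= 0 or self.psf_sigma < 0:
            raise ValueError("pixel_size must be > 0 and psf_sigma >= 0")
        for lo, hi in (self.tubule_diameter, self.tubule_length,
                       self.bulb_min_diameter, self.bulb_axis_ratio):
            if not (0 < lo <= hi):
                raise ValueError("ranges must satisfy 0 < low <= high")
        if self.bulb_axis_ratio[0] < 1:
            raise ValueError("axis ratios must be >= 1")
        if self.bulb_min_diameter[0] < 2 * self.tubule_diameter[1]:
            raise ValueError("bulb and tubule diameter classes must be separable "
                             "(bulb lower bound >= 2x tubule upper bound)")
        for p in (self.edu_probability,
                  self.edu_probability_clustered if self.edu_probability_clustered
                  is not None else 0.0):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.nucleoids_per_bulb[0] < 1 or \
                self.nucleoids_per_bulb[0] > self.nucleoids_per_bulb[1]:
            raise ValueError("nucleoids_per_bulb must be a valid integer range")
        if self.nucleoid_spacing_tubule <= 0:
            raise ValueError("nucleoid spacing must be > 0")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def field_um(self) -> float:
        return self.image_size * self.pixel_size

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParams":
        kw = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kw[f.name] = tuple(v) if isinstance(v, (list, tuple)) else v
        p = cls(**kw)
        p.validate()
        return p


@dataclass
class Organelle:
    organelle_id: int
    cell_id: int
    cls: str  # "tubular" | "bulb"
    polygon: Polygon
    min_diameter: float  # um; tubule width or bulb minor diameter
    tmrm_factor: float
    ox_ratio: float

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class Nucleoid:
    nucleoid_id: int
    organelle_id: int
    x: float
    y: float
    edu_positive: bool


@dataclass
class GroundTruthScene:
    """Latent scene description: the oracle for every recovery test."""

    params: SceneParams
    cells: list[tuple[int, Polygon]]
    organelles: list[Organelle]
    nucleoids: list[Nucleoid]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def organelle(self, organelle_id: int) -> Organelle:
        return self._by_id[organelle_id]

    def __post_init__(self) -> None:
        self._by_id = {o.organelle_id: o for o in self.organelles}

    def bulbs(self) -> list[Organelle]:
        return [o for o in self.organelles if o.cls == "bulb"]

    def tubules(self) -> list[Organelle]:
        return [o for o in self.organelles if o.cls == "tubular"]

    def nucleoids_of(self, organelle_id: int) -> list[Nucleoid]:
        return [n for n in self.nucleoids if n.organelle_id == organelle_id]

    def to_json(self) -> str:
        def poly(p: Polygon):
            return [[round(x, 6), round(y, 6)] for x, y in p.exterior.coords]
        doc = {
            "params": dataclasses.asdict(self.params),
            "cells": [{"cell_id": c, "polygon": poly(p)} for c, p in self.cells],
            "organelles": [
                {"organelle_id": o.organelle_id, "cell_id": o.cell_id,
                 "class": o.cls, "polygon": poly(o.polygon),
                 "area_um2": round(o.area, 6),
                 "min_diameter_um": round(o.min_diameter, 6),
                 "tmrm_factor": o.tmrm_factor, "ox_ratio": o.ox_ratio}
                for o in self.organelles],
            "nucleoids": [
                {"nucleoid_id": n.nucleoid_id, "organelle_id": n.organelle_id,
                 "x_um": round(n.x, 6), "y_um": round(n.y, 6),
                 "edu_positive": bool(n.edu_positive)}
                for n in self.nucleoids],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthScene":
        doc = json.loads(text)
        params = SceneParams.from_dict(doc["params"])
        cells = [(c["cell_id"], Polygon(c["polygon"])) for c in doc["cells"]]
        orgs = [Organelle(o["organelle_id"], o["cell_id"], o["class"],
                          Polygon(o["polygon"]), o["min_diameter_um"],
                          o["tmrm_factor"], o["ox_ratio"])
                for o in doc["organelles"]]
        nucs = [Nucleoid(n["nucleoid_id"], n["organelle_id"], n["x_um"],
                         n["y_um"], n["edu_positive"])
                for n in doc["nucleoids"]]
        return cls(params, cells, orgs, nucs)


# ---------------------------------------------------------------------------
# scene generation

def _cell_tiles(params: SceneParams) -> list[tuple[int, Polygon]]:
    """Tile the field into n_cells rectangular cell territories."""
    n = params.n_cells
    ncol = int(math.ceil(math.sqrt(n)))
    nrow = int(math.ceil(n / ncol))
    w, h = params.field_um / ncol, params.field_um / nrow
    cells = []
    margin = 0.3
    for i in range(n):
        r, c = divmod(i, ncol)
        cells.append((i + 1, box(c * w + margin, r * h + margin,
                                 (c + 1) * w - margin, (r + 1) * h - margin)))
    return cells


def _bulb_polygon(center, minor_d, ratio, angle) -> Polygon:
    circ = Point(center).buffer(0.5, quad_segs=48)
    ell = affinity.scale(circ, xfact=minor_d * ratio, yfact=minor_d)
    return affinity.rotate(ell, angle, use_radians=True)


def _tubule_path(rng, start, length, step=0.8, bend_sd=0.5) -> LineString:
    pts = [np.asarray(start, float)]
    theta = rng.uniform(0, 2 * np.pi)
    remaining = length
    while remaining > 1e-9:
        s = min(step, remaining)
        pts.append(pts[-1] + s * np.array([np.cos(theta), np.sin(theta)]))
        theta += rng.normal(0.0, bend_sd)
        remaining -= s
    return LineString(pts)


def _place(make_candidate, cell: Polygon, placed, max_tries=300):
    """Rejection-sample a candidate (polygon, meta) until it fits disjointly."""
    for _ in range(max_tries):
        poly, meta = make_candidate()
        if not poly.within(cell):
            continue
        if all(poly.distance(q) > _CLEARANCE_UM for q in placed):
            return poly, meta
    raise PlacementError("could not place organelle disjointly after "
                         f"{max_tries} attempts; reduce counts or sizes")


def generate_scene(params: SceneParams, seed: int | None = None) -> GroundTruthScene:
    """Generate a ground-truth scene; deterministic for fixed (params, seed)."""
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    geom_rng, nuc_rng, edu_rng = (np.random.default_rng(s)
                                  for s in rng.integers(0, 2**31 - 1, 3))
    cells = _cell_tiles(params)
    organelles: list[Organelle] = []
    oid = 0
    for cell_id, cell in cells:
        placed: list[Polygon] = []
        minx, miny, maxx, maxy = cell.bounds
        # bulbs first (largest objects pack worst)
        for _ in range(params.bulbs_per_cell):
            def cand():
                d = geom_rng.uniform(*params.bulb_min_diameter)
                r = geom_rng.uniform(*params.bulb_axis_ratio)
                ang = geom_rng.uniform(0, np.pi)
                c = (geom_rng.uniform(minx, maxx), geom_rng.uniform(miny, maxy))
                return _bulb_polygon(c, d, r, ang), d
            poly, minor_d = _place(cand, cell, placed)
            placed.append(poly)
            oid += 1
            organelles.append(Organelle(oid, cell_id, "bulb", poly, minor_d,
                                        params.tmrm_factor_bulb,
                                        params.ox_ratio_bulb))
        for _ in range(params.tubules_per_cell):
            def cand():
                w = geom_rng.uniform(*params.tubule_diameter)
                L = geom_rng.uniform(*params.tubule_length)
                start = (geom_rng.uniform(minx, maxx), geom_rng.uniform(miny, maxy))
                path = _tubule_path(geom_rng, start, L)
                return path.buffer(w / 2, quad_segs=16), (path, w)
            poly, (path, width) = _place(cand, cell, placed)
            placed.append(poly)
            oid += 1
            org = Organelle(oid, cell_id, "tubular", poly, width,
                            params.tmrm_factor_tubular, params.ox_ratio_tubular)
            org.midline = path  # kept for nucleoid placement & trace planning
            organelles.append(org)

    nucleoids: list[Nucleoid] = []
    nid = 0
    for org in organelles:
        if org.cls == "bulb":
            n = int(nuc_rng.integers(params.nucleoids_per_bulb[0],
                                     params.nucleoids_per_bulb[1] + 1))
            pts = _sample_in_polygon(nuc_rng, org.polygon, n)
        else:
            path: LineString = org.midline
            spacing = params.nucleoid_spacing_tubule
            pos, pts = nuc_rng.uniform(0, spacing), []
            while pos < path.length:
                p = path.interpolate(pos)
                pts.append((p.x, p.y))
                pos += spacing * max(0.3, 1 + nuc_rng.normal(0, 0.15))
        for (x, y) in pts:
            nid += 1
            nucleoids.append(Nucleoid(nid, org.organelle_id, x, y, False))

    # EdU flags: i.i.d. Bernoulli; optionally a different rate inside bulbs
    p_clu = (params.edu_probability if params.edu_probability_clustered is None
             else params.edu_probability_clustered)
    by_id = {o.organelle_id: o for o in organelles}
    for n in nucleoids:
        p = p_clu if by_id[n.organelle_id].cls == "bulb" else params.edu_probability
        n.edu_positive = bool(edu_rng.random() < p)

    return GroundTruthScene(params, cells, organelles, nucleoids)


def _sample_in_polygon(rng, poly: Polygon, n: int,
                       margin: float = _NUCLEOID_MARGIN_UM,
                       min_sep: float = _NUCLEOID_MIN_SEP_UM) -> list[tuple]:
    inner = poly.buffer(-margin)
    if inner.is_empty:
        inner = poly
    minx, miny, maxx, maxy = inner.bounds
    pts: list[tuple] = []
    tries = 0
    while len(pts) < n and tries < 4000:
        tries += 1
        x, y = rng.uniform(minx, maxx), rng.uniform(miny, maxy)
        if not inner.contains(Point(x, y)):
            continue
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in pts):
            pts.append((x, y))
    if len(pts) < n:  # crowded bulb: relax separation rather than fail
        while len(pts) < n:
            x, y = rng.uniform(minx, maxx), rng.uniform(miny, maxy)
            if inner.contains(Point(x, y)):
                pts.append((x, y))
    return pts


# ---------------------------------------------------------------------------
# rendering

def _rasterize(poly: Polygon, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Binary pixel-center rasterization of a polygon given in um coordinates."""
    from skimage.draw import polygon as draw_polygon
    xy = np.asarray(poly.exterior.coords) / pixel_size
    rr, cc = draw_polygon(xy[:, 1], xy[:, 0], shape=shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    for ring in poly.interiors:
        ixy = np.asarray(ring.coords) / pixel_size
        rr, cc = draw_polygon(ixy[:, 1], ixy[:, 0], shape=shape)
        mask[rr, cc] = False
    return mask


def _add_spot(img: np.ndarray, x_px: float, y_px: float, amp: float,
              sigma_px: float) -> None:
    if sigma_px <= 0:
        iy, ix = int(round(y_px)), int(round(x_px))
        if 0 <= iy < img.shape[0] and 0 <= ix < img.shape[1]:
            img[iy, ix] += amp
        return
    r = int(math.ceil(4 * sigma_px))
    y0, y1 = max(0, int(y_px) - r), min(img.shape[0], int(y_px) + r + 1)
    x0, x1 = max(0, int(x_px) - r), min(img.shape[1], int(x_px) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((xx - x_px) ** 2 + (yy - y_px) ** 2) / (2 * sigma_px**2))


def render_image(scene: GroundTruthScene,
                 channels: tuple[str, ...] = CHANNELS,
                 noise: bool = True,
                 seed: int = 0) -> dict[str, np.ndarray]:
    """Render the scene into float photon-count channel images.

    The matrix (EGFP) channel is a constant photon density on organelle
    interiors; TMRM scales it by each organelle's tmrm_factor; the roGFP2
    pair splits a constant pool so that 405/488 equals the organelle's
    ox_ratio pixelwise; DNA/EdU are Gaussian spots at nucleoid positions.
    PSF blur precedes noise; Poisson shot noise on (signal + background) is
    followed by additive Gaussian read noise.
    """
    p = scene.params
    unknown = set(channels) - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    shape = (p.image_size, p.image_size)
    sigma_px = p.psf_sigma / p.pixel_size
    rng = np.random.default_rng(seed)

    extended = {c: np.zeros(shape) for c in channels
                if c in ("egfp", "tmrm", "rogfp405", "rogfp488")}
    if extended:
        for org in scene.organelles:
            mask = _rasterize(org.polygon, shape, p.pixel_size)
            if "egfp" in extended:
                extended["egfp"][mask] += p.egfp_density
            if "tmrm" in extended:
                extended["tmrm"][mask] += org.tmrm_factor * p.egfp_density
            if "rogfp405" in extended:
                extended["rogfp405"][mask] += \
                    2 * p.egfp_density * org.ox_ratio / (1 + org.ox_ratio)
            if "rogfp488" in extended:
                extended["rogfp488"][mask] += \
                    2 * p.egfp_density / (1 + org.ox_ratio)
        if sigma_px > 0:
            for c in extended:
                extended[c] = gaussian_filter(extended[c], sigma_px)

    out: dict[str, np.ndarray] = {}
    for c in channels:
        img = extended.get(c, np.zeros(shape)).copy() if c in extended \
            else np.zeros(shape)
        if c in ("dna", "edu"):
            spot_sigma = max(sigma_px, 0.0)
            for n in scene.nucleoids:
                if c == "edu" and not n.edu_positive:
                    continue
                _add_spot(img, n.x / p.pixel_size, n.y / p.pixel_size,
                          p.nucleoid_peak_photons, spot_sigma)
        img = img + p.background_level
        if noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if p.read_noise_sd > 0:
                img = img + rng.normal(0, p.read_noise_sd, shape)
        out[c] = img
    return out


# ---------------------------------------------------------------------------
# STORM localization lists

@dataclass(frozen=True)
class StormParams:
    """Synthetic single-molecule localization model (nm units)."""

    locs_per_nucleoid: tuple[int, int] = (500, 2000)
    localization_precision: float = 13.0
    background_locs_per_um2: float = 0.0
    semidiameter_mean: float = 75.3
    semidiameter_sd: float = 19.6
    ellipticity_mean: float = 1.48
    ellipticity_sd: float = 0.24
    field_size_um: float = 10.0
    photons_range: tuple[float, float] = (1200.0, 1800.0)
    seed: int = 0

    def validate(self) -> None:
        if self.localization_precision < 0:
            raise ValueError("localization precision must be >= 0")
        if self.semidiameter_mean <= 0:
            raise ValueError("semidiameter mean must be > 0")
        if self.ellipticity_mean < 1:
            raise ValueError("ellipticity mean must be >= 1")
        if self.locs_per_nucleoid[0] < 1 or \
                self.locs_per_nucleoid[0] > self.locs_per_nucleoid[1]:
            raise ValueError("locs_per_nucleoid must be a valid integer range")
        if self.background_locs_per_um2 < 0 or self.field_size_um <= 0:
            raise ValueError("background density and field size must be valid")

    @classmethod
    def from_dict(cls, d: dict) -> "StormParams":
        kw = {f.name: (tuple(d[f.name]) if isinstance(d[f.name], (list, tuple))
                       else d[f.name])
              for f in dataclasses.fields(cls) if f.name in d}
        p = cls(**kw)
        p.validate()
        return p


def generate_localizations(params: StormParams, n_nucleoids: int = 24,
                           seed: int | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate localization clouds for isolated elliptical nucleoids.

    Each nucleoid's (semi-diameter, ellipticity) pair is drawn from the
    configured population; emitters are placed uniformly within the ellipse
    and jittered by an isotropic Gaussian of SD = localization_precision.
    Cluster centers sit on a jittered grid so clusters stay isolated.

    Returns (localizations, truth): the localization table with columns
    ``id,x_nm,y_nm,z_nm,photons,frame,cluster_id`` and a per-cluster truth
    table of generating shape parameters.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    field_nm = params.field_size_um * 1000.0

    ncol = int(math.ceil(math.sqrt(n_nucleoids)))
    pitch = field_nm / ncol
    rows = []
    truth = []
    loc_id = 0
    for k in range(n_nucleoids):
        r, c = divmod(k, ncol)
        cx = (c + 0.5) * pitch + rng.uniform(-0.08, 0.08) * pitch
        cy = (r + 0.5) * pitch + rng.uniform(-0.08, 0.08) * pitch
        s = max(rng.normal(params.semidiameter_mean, params.semidiameter_sd), 15.0)
        e = max(rng.normal(params.ellipticity_mean, params.ellipticity_sd), 1.0)
        d_min = 4 * s / (1 + e)
        a, b = e * d_min / 2, d_min / 2  # semi-major, semi-minor (nm)
        ang = rng.uniform(0, np.pi)
        n = int(rng.integers(params.locs_per_nucleoid[0],
                             params.locs_per_nucleoid[1] + 1))
        th = rng.uniform(0, 2 * np.pi, n)
        rad = np.sqrt(rng.uniform(0, 1, n))
        ex, ey = a * rad * np.cos(th), b * rad * np.sin(th)
        x = cx + ex * np.cos(ang) - ey * np.sin(ang)
        y = cy + ex * np.sin(ang) + ey * np.cos(ang)
        if params.localization_precision > 0:
            x = x + rng.normal(0, params.localization_precision, n)
            y = y + rng.normal(0, params.localization_precision, n)
        for xi, yi in zip(x, y):
            loc_id += 1
            rows.append((loc_id, xi, yi, 0.0,
                         rng.uniform(*params.photons_range), loc_id, k + 1))
        truth.append({"cluster_id": k + 1, "x_nm": cx, "y_nm": cy,
                      "semi_diameter_nm": s, "ellipticity": e,
                      "d_min_nm": d_min, "d_max_nm": e * d_min, "n_locs": n})

    n_bg = rng.poisson(params.background_locs_per_um2 * params.field_size_um**2)
    for _ in range(n_bg):
        loc_id += 1
        rows.append((loc_id, rng.uniform(0, field_nm), rng.uniform(0, field_nm),
                     0.0, rng.uniform(*params.photons_range), loc_id, 0))

    locs = pd.DataFrame(rows, columns=["id", "x_nm", "y_nm", "z_nm",
                                       "photons", "frame", "cluster_id"])
    return locs, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# trace planning (emulates manual placement of 5-um bisecting traces)

def plan_traces(scene: GroundTruthScene, length_um: float = 5.0,
                max_per_class_per_cell: int | None = None,
                n_background: int = 2, seed: int = 0) -> list[dict]:
    """Plan line-trace endpoints bisecting organelles, plus background traces.

    Bulb traces pass through the bulb centroid at a random angle; tubular
    traces cross the tubule perpendicular to its midline at a random arc
    position.  Background traces are placed in vacant areas at least 1 um
    from any organelle.  Returns rows with keys
    trace_id, cell_id, class, x0_um, y0_um, x1_um, y1_um.
    """
    rng = np.random.default_rng(seed)
    p = scene.params
    fmax = p.field_um
    rows: list[dict] = []
    per_cell_count: dict[tuple[int, str], int] = {}

    margin = 2 * p.pixel_size  # keep endpoints on valid pixel centers

    def clamp_segment(cx, cy, dx, dy):
        half = length_um / 2
        x0, y0 = cx - half * dx, cy - half * dy
        x1, y1 = cx + half * dx, cy + half * dy
        if min(x0, x1, y0, y1) < margin or max(x0, x1, y0, y1) > fmax - margin:
            return None
        return (x0, y0, x1, y1)

    for org in scene.organelles:
        key = (org.cell_id, org.cls)
        if (max_per_class_per_cell is not None
                and per_cell_count.get(key, 0) >= max_per_class_per_cell):
            continue
        seg = None
        for _ in range(20):
            if org.cls == "bulb":
                c = org.polygon.centroid
                ang = rng.uniform(0, np.pi)
                seg = clamp_segment(c.x, c.y, np.cos(ang), np.sin(ang))
            else:
                path = getattr(org, "midline", None)
                if path is None:
                    c = org.polygon.centroid
                    ang = rng.uniform(0, np.pi)
                    seg = clamp_segment(c.x, c.y, np.cos(ang), np.sin(ang))
                else:
                    s = rng.uniform(0.2, 0.8) * path.length
                    pt = path.interpolate(s)
                    ahead = path.interpolate(min(s + 0.1, path.length))
                    tx, ty = ahead.x - pt.x, ahead.y - pt.y
                    norm = math.hypot(tx, ty) or 1.0
                    seg = clamp_segment(pt.x, pt.y, -ty / norm, tx / norm)
            if seg is not None:
                break
        if seg is None:
            continue
        per_cell_count[key] = per_cell_count.get(key, 0) + 1
        rows.append({"trace_id": f"tr{len(rows) + 1}",
                     "cell_id": f"cell{org.cell_id}", "class": org.cls,
                     "x0_um": seg[0], "y0_um": seg[1],
                     "x1_um": seg[2], "y1_um": seg[3]})

    from shapely.ops import unary_union
    occupied = unary_union([o.polygon for o in scene.organelles]).buffer(1.0)
    placed = 0
    for _ in range(200):
        if placed >= n_background:
            break
        cx, cy = rng.uniform(2, fmax - 2, 2)
        seg = clamp_segment(cx, cy, 1.0, 0.0)
        if seg is None:
            continue
        line = LineString([(seg[0], seg[1]), (seg[2], seg[3])])
        if line.intersects(occupied):
            continue
        placed += 1
        rows.append({"trace_id": f"bg{placed}", "cell_id": "background",
                     "class": "background", "x0_um": seg[0], "y0_um": seg[1],
                     "x1_um": seg[2], "y1_um": seg[3]})
    return rows
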