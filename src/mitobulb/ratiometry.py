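"""Line-trace ratiometry (TMRM:EGFP membrane-potential proxy, MitoSOX) and
pixelwise roGFP2 oxidized:reduced ratio maps.

A trace is a 5-um segment bisecting one organelle, sampled identically in
two channels by bilinear interpolation.  Each trace is quantified as the
area under the background-subtracted profile between the left and right
half-maximum crossings of the peak; the per-trace statistic is the ratio of
the two channel AUCs.  By default both channels are integrated over the
window defined by the denominator (matrix-reporter) channel's half-max
crossings so numerator and denominator cover the same physical span; the
per-channel-window variant is selectable.  Cross-cell summaries weight each
cell by its trace count, and bulb vs tubular ratios are compared with
Welch's t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .stats_report import StatResult, welch_t

__all__ = [
    "LineTrace",
    "HalfMaxResult",
    "TraceQuant",
    "RatioMap",
    "extract_trace",
    "halfmax_auc",
    "halfmax_window",
    "auc_between",
    "trace_ratio_comparison",
    "ratio_map",
]

TRACE_CLASSES = ("bulb", "tubular", "background")


@dataclass
class LineTrace:
    trace_id: str
    cell_id: str
    cls: str  # "bulb" | "tubular" | "background"
    p0: tuple[float, float]  # um
    p1: tuple[float, float]  # um
    sample_spacing: float  # um
    channel_a: np.ndarray  # e.g. TMRM / MitoSOX / roGFP-405
    channel_b: np.ndarray  # e.g. EGFP / roGFP-488
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.cls not in TRACE_CLASSES:
            raise ValueError(f"class must be one of {TRACE_CLASSES}")
        self.channel_a = np.asarray(self.channel_a, dtype=float)
        self.channel_b = np.asarray(self.channel_b, dtype=float)
        if self.channel_a.shape != self.channel_b.shape:
            raise ValueError("channels must have equal sample counts")
        if not self.image_id:
            self.image_id = self.cell_id

    @property
    def length(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))


def extract_trace(image_a: np.ndarray, image_b: np.ndarray,
                  p0_um, p1_um, pixel_size: float,
                  spacing_um: float | None = None,
                  trace_id: str = "t0", cell_id: str = "c0",
                  cls: str = "tubular", image_id: str = "") -> LineTrace:
    """Sample both channels along a segment with bilinear interpolation.

    Sample positions are identical for the two channels, uniformly spaced at
    ``spacing_um`` (default half a pixel) from p0 to p1 inclusive.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("images must be 2D with identical shapes")
    if spacing_um is None:
        spacing_um = pixel_size / 2
    if spacing_um > pixel_size:
        raise ValueError("spacing must be <= pixel_size")
    p0 = np.asarray(p0_um, dtype=float)
    p1 = np.asarray(p1_um, dtype=float)
    hmax = (np.array(a.shape[::-1]) - 1) * pixel_size
    for p in (p0, p1):
        if (p < 0).any() or (p > hmax).any():
            raise ValueError("trace endpoints fall outside the image")
    length = float(np.hypot(*(p1 - p0)))
    n = max(int(round(length / spacing_um)) + 1, 2)
    ts = np.linspace(0.0, 1.0, n)
    xy = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    coords = np.stack([xy[:, 1] / pixel_size, xy[:, 0] / pixel_size])
    va = map_coordinates(a, coords, order=1, mode="nearest")
    vb = map_coordinates(b, coords, order=1, mode="nearest")
    return LineTrace(trace_id, cell_id, cls, tuple(p0), tuple(p1),
                     length / (n - 1), va, vb, image_id=image_id)


@dataclass
class HalfMaxResult:
    auc: float  # intensity * um
    left: float | None  # crossing positions in samples (fractional index)
    right: float | None
    peak_index: int
    valid: bool
    truncated: bool


def halfmax_window(profile: np.ndarray, background_level: float = 0.0,
                   ) -> HalfMaxResult:
    """Locate the half-maximum window of the global peak.

    Background is subtracted, the global maximum located, and the nearest
    left/right half-maximum crossings found by linear interpolation.  A peak
    not rising above background is flagged invalid; a missing crossing (peak
    running into a trace edge) marks the window truncated at that edge.
    """
    p = np.asarray(profile, dtype=float) - background_level
    if len(p) < 3:
        raise ValueError("profile needs >= 3 samples")
    imax = int(np.argmax(p))
    peak = p[imax]
    if peak <= 0:
        return HalfMaxResult(0.0, None, None, imax, False, False)
    half = peak / 2

    left = None
    for i in range(imax, 0, -1):
        if p[i - 1] < half <= p[i]:
            left = (i - 1) + (half - p[i - 1]) / (p[i] - p[i - 1])
            break
    right = None
    for i in range(imax, len(p) - 1):
        if p[i] >= half > p[i + 1]:
            right = i + (p[i] - half) / (p[i] - p[i + 1])
            break
    truncated = left is None or right is None
    return HalfMaxResult(0.0, left if left is not None else 0.0,
                         right if right is not None else float(len(p) - 1),
                         imax, True, truncated)


def auc_between(profile: np.ndarray, background_level: float,
                left: float, right: float, spacing: float = 1.0) -> float:
    """Trapezoidal integral of (profile - background) over [left, right]
    (fractional sample indices), scaled by the sample spacing."""
    p = np.asarray(profile, dtype=float) - background_level
    idx = np.arange(len(p), dtype=float)
    xs = np.concatenate(([left], idx[(idx > left) & (idx < right)], [right]))
    ys = np.interp(xs, idx, p)
    return float(np.trapezoid(ys, xs)) * spacing


def halfmax_auc(profile: np.ndarray, background_level: float = 0.0,
                spacing: float = 1.0) -> HalfMaxResult:
    """AUC of the background-subtracted profile between the half-max
    crossings of its global peak (trapezoidal integration)."""
    win = halfmax_window(profile, background_level)
    if not win.valid:
        return win
    win.auc = auc_between(profile, background_level, win.left, win.right,
                          spacing)
    return win


@dataclass
class TraceQuant:
    per_trace: pd.DataFrame
    cell_means: pd.DataFrame
    mean_bulb: float
    mean_tubular: float
    relative_reduction_percent: float
    welch: StatResult
    n_traces: dict
    n_cells: int
    window_mode: str
    background: dict
    excluded: list = field(default_factory=list)


def trace_ratio_comparison(traces: list[LineTrace],
                           background_traces: list[LineTrace] | None = None,
                           window_mode: str = "shared",
                           ratio_floor: float | None = None) -> TraceQuant:
    """Compare bulb vs tubular channel-A:channel-B AUC ratios.

    Per image, the background level per channel is the mean of that image's
    background traces.  Per trace, AUCs are taken over the channel-B half-max
    window ("shared", default) or over each channel's own window
    ("per-channel"); the ratio is AUC_a / AUC_b.  Per-cell class means are
    combined across cells weighted by the cell's trace count; the relative
    reduction is 100 * (1 - mean_bulb / mean_tubular).  Welch's t compares
    the per-trace ratios of the two classes.  Traces with no positive peak,
    or with ratios below ``ratio_floor`` (depolarized outliers), are excluded
    and listed.
    """
    if window_mode not in ("shared", "per-channel"):
        raise ValueError("window_mode must be 'shared' or 'per-channel'")
    fg = [t for t in traces if t.cls in ("bulb", "tubular")]
    bgs = ([t for t in traces if t.cls == "background"]
           + list(background_traces or []))
    bg_by_image: dict[str, tuple[float, float]] = {}
    for img in {t.image_id for t in fg}:
        mine = [t for t in bgs if t.image_id == img] or bgs
        if mine:
            bg_a = float(np.mean(np.concatenate([t.channel_a for t in mine])))
            bg_b = float(np.mean(np.concatenate([t.channel_b for t in mine])))
        else:
            bg_a = bg_b = 0.0
        bg_by_image[img] = (bg_a, bg_b)

    rows, excluded = [], []
    for t in fg:
        bg_a, bg_b = bg_by_image[t.image_id]
        win_b = halfmax_window(t.channel_b, bg_b)
        if not win_b.valid:
            excluded.append((t.trace_id, "no positive channel_b peak"))
            continue
        auc_b = auc_between(t.channel_b, bg_b, win_b.left, win_b.right,
                            t.sample_spacing)
        if window_mode == "shared":
            auc_a = auc_between(t.channel_a, bg_a, win_b.left, win_b.right,
                                t.sample_spacing)
        else:
            win_a = halfmax_window(t.channel_a, bg_a)
            if not win_a.valid:
                excluded.append((t.trace_id, "no positive channel_a peak"))
                continue
            auc_a = auc_between(t.channel_a, bg_a, win_a.left, win_a.right,
                                t.sample_spacing)
        if auc_b <= 0 or auc_a <= 0:
            excluded.append((t.trace_id, "nonpositive AUC"))
            continue
        ratio = auc_a / auc_b
        if ratio_floor is not None and ratio < ratio_floor:
            excluded.append((t.trace_id, f"ratio {ratio:.3g} below floor"))
            continue
        rows.append({"trace_id": t.trace_id, "cell_id": t.cell_id,
                     "image_id": t.image_id, "class": t.cls,
                     "auc_a": auc_a, "auc_b": auc_b, "ratio": ratio,
                     "truncated": win_b.truncated})
    per_trace = pd.DataFrame(rows)
    if per_trace.empty or per_trace["class"].nunique() < 2:
        raise ValueError("need valid traces of both classes")

    cell_means = (per_trace.groupby(["cell_id", "class"])["ratio"]
                  .agg(mean="mean", n="count").reset_index())
    # cells lacking one class are excluded from the paired comparison
    have_both = (cell_means.groupby("cell_id")["class"].nunique() == 2)
    paired_cells = set(have_both[have_both].index)
    for c in set(cell_means["cell_id"]) - paired_cells:
        excluded.append((f"cell:{c}", "cell lacks one trace class"))
    paired = cell_means[cell_means["cell_id"].isin(paired_cells)]

    def wmean(cls: str) -> float:
        g = paired[paired["class"] == cls]
        return float(np.average(g["mean"], weights=g["n"]))

    mean_bulb, mean_tub = wmean("bulb"), wmean("tubular")
    rel = 100.0 * (1.0 - mean_bulb / mean_tub)
    w = welch_t(per_trace.loc[per_trace["class"] == "tubular", "ratio"],
                per_trace.loc[per_trace["class"] == "bulb", "ratio"])
    n_traces = per_trace["class"].value_counts().to_dict()
    return TraceQuant(per_trace=per_trace, cell_means=cell_means,
                      mean_bulb=mean_bulb, mean_tubular=mean_tub,
                      relative_reduction_percent=rel, welch=w,
                      n_traces=n_traces, n_cells=len(paired_cells),
                      window_mode=window_mode,
                      background={k: {"channel_a": v[0], "channel_b": v[1]}
                                  for k, v in sorted(bg_by_image.items())},
                      excluded=excluded)


@dataclass
class RatioMap:
    ratio: np.ndarray  # NaN where invalid
    valid_mask: np.ndarray
    intensity_floor: float
    organelle_medians: dict | None = None


def ratio_map(image_405: np.ndarray, image_488: np.ndarray,
              mito_mask: np.ndarray | None = None,
              intensity_floor: float = 0.0,
              labels: np.ndarray | None = None) -> RatioMap:
    """Pixelwise oxidized:reduced (405/488) ratio on the mitochondrial mask.

    A pixel is valid where the denominator exceeds ``intensity_floor`` and
    (if given) the mask is set.  With a label image, per-organelle median
    ratios are reported.
    """
    a = np.asarray(image_405, dtype=float)
    b = np.asarray(image_488, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    valid = b > intensity_floor
    if mito_mask is not None:
        if mito_mask.shape != a.shape:
            raise ValueError("mask shape differs from images")
        valid &= mito_mask.astype(bool)
    ratio = np.full(a.shape, np.nan)
    ratio[valid] = a[valid] / b[valid]
    medians = None
    if labels is not None:
        medians = {}
        for lab in np.unique(labels):
            if lab == 0:
                continue
            sel = (labels == lab) & valid
            medians[int(lab)] = float(np.median(ratio[sel])) if sel.any() \
                else float("nan")
    return RatioMap(ratio, valid, intensity_floor, medians)
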