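# Methods

This note documents the models, conventions and numerical choices behind
each stage of the package, the assumptions of the synthetic-data generator,
and the limits of what validation on synthetic scenes demonstrates.

## Synthetic scenes (simgen)

**Geometry.** The field (default 512 px at 0.06 µm/px, ≈ 30.7 µm) is tiled
into rectangular cell territories.  Tubular mitochondria are modeled as
constant-width smooth random curves: a polyline grown in ~0.8 µm steps with
Gaussian heading changes (SD 0.5 rad), buffered to a width drawn from
U(0.4, 0.5) µm; total length U(2, 5) µm.  Mito-bulbs are ellipses with minor
diameter U(1.2, 5.0) µm and axis ratio U(1.0, 1.8) at random orientation —
swollen mitochondria present near-spherical to moderately oblate profiles,
and the 1.8 cap keeps an ideal ellipse's circularity ≥ 0.88, comfortably
above the 0.8 scoring cutoff so that class membership is decided by size,
not eccentricity.  Organelles are placed by rejection sampling with a 0.2 µm
clearance inside their cell; an impossible packing raises an explicit
placement error after bounded retries.

**Nucleoids.** Tubules carry nucleoids along the midline at ~1 µm mean
spacing (jittered ±15%), emulating regularly spaced single nucleoids.  Each
bulb holds an integer count drawn from U{3..6}, placed uniformly inside the
ellipse with a 0.25 µm minimum separation (discrete nucleoids that do not
merge).  EdU (replication) flags are i.i.d. Bernoulli(0.4) regardless of
cluster status — the generator's null hypothesis; a separate bulb-specific
probability is available for power studies.

**Physiology.** Each organelle carries a TMRM factor (bulb 0.8, tubule 1.0:
a 20% lower membrane-potential proxy per unit matrix reporter) and an
oxidized:reduced roGFP2 ratio (bulb 2.0, tubule 1.0).

**Rendering.** Intensity units are photons.  The matrix (EGFP) channel is a
constant density (120 photons/px) on organelle interiors; TMRM multiplies it
by the organelle's TMRM factor; the roGFP2 channel pair splits 2× the
matrix density so that 405/488 equals the organelle's oxidation ratio
pixelwise.  Extended structures are blurred with a Gaussian PSF
(σ = 0.12 µm); nucleoids, being sub-diffraction, are drawn directly as 2D
Gaussian spots of SD = σ_PSF (peak 400 photons).  Background (5 photons/px)
is added, then Poisson shot noise on (signal + background), then additive
Gaussian read noise (SD 2) — the standard sCMOS/EMCCD forward model.
Rasterization is pixel-center point sampling; flux is conserved by the
normalized PSF (verified to 2%).

**Localization lists.** Each synthetic nucleoid draws its semi-diameter s
from N(75.3, 19.6²) nm (floored at 15 nm) and ellipticity e from
N(1.48, 0.24²) (floored at 1); the ellipse axes follow from
d_min = 4s/(1+e), d_max = e·d_min.  Emitters (U{500..2000} per nucleoid)
are uniform inside the ellipse, then jittered by an isotropic Gaussian of
SD 13 nm (the localization precision); photon counts are U(1200, 1800).
Cluster centers sit on a jittered grid so clusters are isolated; uniform
background localizations are optional.

**Determinism.** Every entry point takes a seed; all child streams derive
from one `numpy.random.default_rng` per call, so identical (params, seed)
give bit-identical scenes, renders and localization tables.

**What the generator does not emulate.** 3D structure and z-stacks (all
quantification here is on 2D sections), cristae substructure, intensity
variation within an organelle, photophysics (blinking, bleaching), sample
drift, optical aberrations, and touching/overlapping organelles (placement
enforces a clearance).  Recovery tests on these scenes therefore validate
the measurement machinery — segmentation geometry, ratio arithmetic,
cluster statistics — not robustness to crowding or model mismatch in real
micrographs.

## Morphometry

Smoothing is a single 3×3 uniform mean filter (reflected borders); on i.i.d.
noise it reduces the SD threefold.  Segmentation thresholds the image
(Otsu by default), seeds a watershed with h-maxima of the intensity
(default dynamic h = 10% of the foreground dynamic range) and floods the
inverted intensity restricted to the foreground, so labels exactly
partition the thresholded foreground; a foreground component without any
seed becomes its own label.  For shot-noise-limited renders of
intensity-flat, well-separated organelles, `segment_noisy` raises the seed
dynamic to 40% of the foreground range after smoothing — on flat objects
every noise maximum is a potential false seed, and splitting here should be
driven by gaps, not intensity dips; this standing rule replaces the
per-image interactive tuning of manual watershed analysis.

Particle features: area = pixel count × pixel_size²; perimeter by the
Crofton formula (4 directions), chosen because it is asymptotically
unbiased for smooth convex outlines — a rasterized disk of radius 20 px
measures circularity 1.008, whereas the naive boundary-polygon length
overestimates smooth perimeters by ~5% at any radius and would bias
circularity to ~0.91.  Circularity 4πA/P² is clamped to 1 within a 5%
rasterization tolerance.  Feret diameters use rotating calipers on the
convex hull of the sub-pixel 0.5-level outer contour: the maximum is the
hull diameter; the minimum is the smallest edge-direction width (exact for
convex polygons).

Mito-bulb incidence counts particles with area strictly above each
threshold **and** circularity ≥ 0.8 (the cutoff is a declared default —
interactive analyses rarely record theirs — and is exposed in the API and
CLI), normalized by the per-image cell count (supplied manually or from a
nuclei channel).  Counts are non-increasing in both the area threshold and
the circularity cutoff by construction.  Multi-image aggregation reports
the across-image mean ± SD of bulbs/cell.  Time-lapse tracking associates
the bulb to the previous centroid within a 1 µm gate and terminates after
more than 3 consecutive misses.

## Nucleoids and replication

Spot detection is Laplacian-of-Gaussian blob detection (σ range 1–3 px,
response floor 8% of the dynamic range by default) with intensity-weighted
sub-pixel refinement in a 5×5 window and duplicate suppression within one
PSF.  A nucleoid inherits the organelle label under its centroid (0 =
background; such nucleoids are excluded from cluster percentages but
reported separately, since the published convention is unstated).  EdU
positivity requires an EdU detection within 150 nm — approximately one
super-resolved spot radius.

Cluster scoring has two variants: count-only (organelle holds ≥ 3 assigned
nucleoids) and count + diameter (additionally min-Feret ≥ 1.2 µm).  The
stricter criterion selects a subset of the looser one.

Replication tables weight per-image EdU⁺ fractions fᵢ by nucleoid counts
Nᵢ: the weighted mean Σ Nᵢfᵢ/Σ Nᵢ is algebraically the pooled fraction.
The SE is the weighted between-image SE,
SE = √( Σ wᵢ(fᵢ − f̄)² / ((M−1) Σ wᵢ) ) with wᵢ = Nᵢ — a declared
convention, since variance-weighted ANOVA formulations differ and the
original weighting is unrecoverable; the formula used is recorded in the
output.  Groups are compared with Student's (equal-variance) t on per-image
fractions, matching the published analysis; Welch's t is used everywhere
else.  Note the all-vs-clustered comparison is conservative under the null
because the clustered arm is nested in the total; the package's null
calibration simulations therefore compare the disjoint (independent)
bulb-resident vs tubule-resident arms, which reject at the nominal 5%.

## Trace ratiometry

Traces are sampled by bilinear interpolation at half-pixel spacing along a
5 µm segment, identically in both channels.  Background per channel is the
scalar mean of the image's background traces (drawn in vacant areas); no
rolling-ball correction.  The half-max window of a profile subtracts
background, takes the global maximum, and finds the nearest left/right
half-maximum crossings by linear interpolation; integration is trapezoidal
between the fractional crossings.  A peak not rising above background is
flagged invalid and excluded; a peak running into a trace end is flagged
truncated.  By default both channels are integrated over the window defined
by the **denominator** (matrix-reporter) channel, so numerator and
denominator cover the same physical span — integrating each channel over
its own window is ambiguous for asymmetric peaks; the per-channel mode is
available and the mode used is recorded in the output.

Per-cell class means are combined across cells with weights proportional to
the cell's trace count; the relative reduction is
100·(1 − mean_bulb/mean_tubular).  This statistic is exactly invariant to
any global gain applied to one channel (the gain cancels in every ratio)
and to background offsets (removed by subtraction).  Traces with ratios
below a configurable floor (apparently depolarized organelles) can be
excluded; exclusions are listed in the output.  Cells lacking one class are
excluded from the paired comparison and logged.  MitoSOX uses the same
path with MitoSOX as channel A; no correction for its DNA-binding artifact
is attempted (the roGFP2 ratio map is the artifact-free alternative).

The roGFP2 map divides the 405 nm by the 488 nm excitation channel
pixelwise on the mitochondrial mask where the denominator exceeds an
intensity floor, and summarizes per-organelle median ratios.  With the
default render (background 5, density 120) the background contributes ~3%
downward bias at ratio 2 — within the 10% recovery tolerance; on real data
background should be subtracted upstream or the floor raised.

## STORM shapes

Density filtering keeps a localization iff at least 10 localizations
(counting itself) fall within 70 nm in XY — a single pass on the original
set; the filter is deliberately not iterated, so the output is not
idempotent under re-filtering (tested as such).  Clustering is
density-based with the same eps/min_pts: clusters are connected components
of core points, numbered by lowest core index; border points join their
nearest core point's cluster (ties to the lowest index).  These rules make
the labeling a pure function of the coordinates and row order; for n ≤ 1000
it matches an O(n²) reference exactly, and its core-point partition agrees
with an independent DBSCAN implementation.

Shape metrics per cluster (Z ignored; 2D): d_min/d_max from rotating
calipers on the XY convex hull, semi-diameter (d_min + d_max)/4 — the mean
of the semi-minor and semi-major extents; an equivalent-circle-radius
variant √(d_min·d_max)/2 is available — and ellipticity d_max/d_min ≥ 1.
Convex-hull extents of jittered point clouds are biased upward: with
~10³ localizations at 13 nm precision the hull's extreme vertices overshoot
the true boundary by tens of nm, inflating a 75 nm mean semi-diameter to
~99 nm.  When the localization precision is known, the `moment` method
instead assumes uniformly labeled ellipsoidal nucleoids observed with
isotropic Gaussian error: the cluster's principal variances are then
λ = (axis/2)²/4 + σ_loc², so d = 4·√(λ − σ_loc²) deconvolves the
localization error (the standard size correction in single-molecule cluster
analysis).  The moment method presumes roughly uniform internal labeling;
for boundary-sampled or hollow structures use the hull method.  Clusters
with < 3 points or no 2D extent are skipped with a reason; clusters within
70 nm of the field border are measured but excluded from population
summaries.

## Statistics and reports

Welch's and Student's two-sample t are computed from the explicit textbook
formulas (Welch–Satterthwaite df for the former), two-sided p-values
throughout, no multiplicity correction.  Zero-variance degeneracies return
t = 0 (equal means) or ±∞ (shifted means) with a degenerate flag rather
than NaN.  Report assembly writes one CSV per stage, a threshold-sweep PNG
when a sweep table is present, and a JSON summary with sorted keys and no
timestamps, so identical runs are byte-identical; seeds and configuration
are embedded.

## Problem sizes used in the packaged studies

The packaged synthetic studies use 24 single-cell images (144 traces) for
the trace-ratiometry recovery, 24 localization clusters (~31k points) for
the STORM recovery, 20 two-cell images for the incidence sweep, and 200
six-image datasets for the null-calibration of the replication test.
These sizes put Monte-Carlo error comfortably inside the stated recovery
tolerances while keeping any single study under a few minutes on one core.

## Known limitations

Segmentation is 2D and assumes organelles separated by at least a PSF-scale
gap; heavily overlapping or out-of-focus structures will merge.  The
incidence statistic depends on the declared circularity cutoff and on
accurate cell counts.  The trace pipeline assumes one dominant peak per
trace; multi-peak traces integrate only the global peak's window.  The
moment shape estimator is model-based (uniform ellipse); its accuracy
degrades for strongly non-uniform labeling.  No drift correction, 3D shape
metrics, or absolute membrane-potential calibration is attempted.
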