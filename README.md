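# mitobulb

Quantitative image analysis of **mito-bulbs** — apparently swollen,
near-spherical mitochondria (minor diameter ≳ 1.2 µm) that hold several
discrete mtDNA nucleoids in one contiguous matrix space, as seen in A549
lung-carcinoma cells alongside normal 0.4–0.5 µm tubular mitochondria.
The package is written for microscopists who need reproducible, scriptable
versions of the measurements usually done interactively in FIJI/NIS — and
for anyone who wants to validate such measurements against images with
known ground truth.

It provides five connected capabilities:

- **simgen** — a ground-truthed synthetic-scene generator: cells containing
  constant-width tubular mitochondria with singly spaced nucleoids and
  elliptical bulbs (minor diameter 1.2–5 µm, ≥ 3 nucleoids each), rendered
  to multi-channel images (matrix EGFP, DNA, EdU, TMRM, roGFP2 405/488) with
  Gaussian PSF, Poisson shot noise and Gaussian read noise at 0.06 µm/pixel;
  plus single-molecule localization lists with configurable precision.
- **morphometry** — h-maxima seeded watershed segmentation of the
  matrix-reporter channel; per-particle area *A*, Crofton perimeter *P*,
  circularity 4π·A/P², rotating-calipers min/max Feret diameters; mito-bulb
  incidence = #{particles with A > t and circularity ≥ 0.8} / n_cells over a
  sweep of area thresholds t; time-lapse tracking of one bulb's minor
  diameter.
- **nucleoids** — Laplacian-of-Gaussian spot detection, organelle
  assignment, cluster scoring (≥ 3 nucleoids in one matrix space, optionally
  also min-Feret ≥ 1.2 µm), and EdU replication tables with count-weighted
  means (mean = Σᵢ Nᵢfᵢ / Σᵢ Nᵢ, i.e. the pooled fraction) and weighted
  between-image SE.
- **ratiometry** — 5 µm line traces sampled in two channels; per-trace
  statistic = AUC_a/AUC_b where both AUCs are trapezoidal integrals of the
  background-subtracted profiles between the half-maximum crossings of the
  denominator (EGFP) peak; bulb-vs-tubular comparison with per-cell
  trace-count weighting and Welch's t; pixelwise oxidized:reduced roGFP2
  ratio maps.
- **storm_shapes** — localization density filtering (keep points with ≥ 10
  molecules within 70 nm), deterministic DBSCAN-style clustering, and
  per-nucleoid shape: d_min/d_max Feret diameters, semi-diameter
  (d_min + d_max)/4 and ellipticity d_max/d_min, with an optional
  localization-precision-corrected moment estimator
  (d = 4·√(λ − σ_loc²) from the principal variances λ of the cluster).

`stats_report` supplies the shared Welch/Student t statistics and assembles
deterministic CSV/JSON/PNG run reports.  A thin `mitobulb` CLI
(`simulate | segment | nucleoids | traces | redox | storm | report`) wraps
the library for shell use; `examples/` holds one narrative script per
capability.

## Worked example

Membrane-potential proxy on synthetic cells whose bulbs accumulate 20% less
TMRM per unit matrix volume (`python examples/03_membrane_potential_traces.py`):

```
traces: {'bulb': 72, 'tubular': 72} from 24 cells
mean TMRM:EGFP ratio, tubular: 0.995
mean TMRM:EGFP ratio, bulb:    0.798
relative reduction: 19.8% (generator physiology: 20%)
Welch's t = 31.53, df = 79.1, p = 1.5e-46
```

The tubular ratio sits at the expected 1.0, the bulb ratio at 0.8, and the
relative reduction 100·(1 − r_bulb/r_tub) recovers the 20% contrast the
generator encoded, decisively separated by Welch's t.

STORM nucleoid shapes (`python examples/05_storm_nucleoid_shapes.py`):

```
24 clusters measured (generated 24)
mean semi-diameter: 75.7 +/- 16.3 nm  (population mean 75.3)
mean ellipticity:   1.55 +/- 0.17     (population mean 1.48)
uncorrected hull estimate: 98.7 nm (localization error pushes hull vertices outward)
```

The precision-corrected estimator recovers the generating population mean;
the raw convex-hull Feret value illustrates why the correction matters at
13 nm localization precision.

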