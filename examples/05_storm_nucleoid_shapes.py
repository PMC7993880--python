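"""STORM nucleoid shape metrics from a synthetic localization list.

Generates 24 isolated nucleoid clusters (population mean semi-diameter
75.3 nm, SD 19.6; ellipticity 1.48) observed at 13 nm localization
precision, filters by local density (>= 10 molecules within 70 nm),
clusters, and measures per-cluster diameters with the precision-corrected
moment estimator.
"""

from mitobulb import simgen, storm_shapes, workflows

summary, truth = workflows.storm_shape_experiment(n_clusters=24, seed=7)

print(f"{summary.n_clusters} clusters measured "
      f"(generated {len(truth)})")
print(f"mean semi-diameter: {summary.mean_semi_diameter:.1f} "
      f"+/- {summary.sd_semi_diameter:.1f} nm  (population mean 75.3)")
print(f"mean ellipticity:   {summary.mean_ellipticity:.2f} "
      f"+/- {summary.sd_ellipticity:.2f}     (population mean 1.48)")

# For comparison, the uncorrected convex-hull Feret diameters of the same
# clusters are inflated by the 13 nm localization jitter:
locs, _ = simgen.generate_localizations(simgen.StormParams(), 24, seed=7)
filt = storm_shapes.density_filter(locs)
labels = storm_shapes.cluster_localizations(filt)
hull = storm_shapes.measure_clusters(filt, labels, method="feret")
print(f"uncorrected hull estimate: {hull.mean_semi_diameter:.1f} nm "
      "(localization error pushes hull vertices outward)")
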