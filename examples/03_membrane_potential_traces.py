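"""Membrane-potential proxy: TMRM:EGFP ratios of bulb vs tubular traces.

Simulates 24 single-cell images whose bulbs accumulate 20% less TMRM per
unit matrix reporter (factor 0.8), draws 5-um traces bisecting bulbs and
tubules plus background traces, and quantifies each trace as the ratio of
the background-subtracted channel AUCs over the EGFP half-max window.
The printed relative reduction should recover ~20%.
"""

from mitobulb import workflows

tq = workflows.tmrm_reduction_experiment(n_cells=24, seed=1)

print(f"traces: {tq.n_traces} from {tq.n_cells} cells")
print(f"mean TMRM:EGFP ratio, tubular: {tq.mean_tubular:.3f}")
print(f"mean TMRM:EGFP ratio, bulb:    {tq.mean_bulb:.3f}")
print(f"relative reduction: {tq.relative_reduction_percent:.1f}% "
      f"(generator physiology: 20%)")
print(f"Welch's t = {tq.welch.statistic:.2f}, df = {tq.welch.df:.1f}, "
      f"p = {tq.welch.p_value:.2g}")
# A reduction near 20% with a decisive p-value shows the ratiometry
# recovers per-organelle membrane-potential contrast despite shot noise.
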