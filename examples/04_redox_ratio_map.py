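"""Pixelwise roGFP2 oxidized:reduced ratio map.

Bulbs are generated twice as oxidized as tubules (ratio 2.0 vs 1.0).  The
405 nm and 488 nm excitation channels are divided pixelwise on the
mitochondrial mask and summarized as per-organelle median ratios.
"""

import numpy as np

from mitobulb import morphometry, ratiometry, simgen

params = simgen.SceneParams(n_cells=1, bulbs_per_cell=2, tubules_per_cell=3)
scene = simgen.generate_scene(params, seed=8)
chans = simgen.render_image(scene, channels=("egfp", "rogfp405", "rogfp488"),
                            noise=True, seed=8)

labels = morphometry.segment_noisy(chans["egfp"], params.pixel_size)
rm = ratiometry.ratio_map(chans["rogfp405"], chans["rogfp488"],
                          mito_mask=labels.labels > 0,
                          intensity_floor=3 * params.background_level,
                          labels=labels.labels)

meds = [m for m in rm.organelle_medians.values() if np.isfinite(m)]
print(f"{int(rm.valid_mask.sum())} valid pixels, "
      f"{len(meds)} organelles measured")
print("per-organelle median oxidized:reduced ratios:",
      [round(m, 2) for m in sorted(meds)])
# Values cluster near 1 (tubules) and near 2 (bulbs): the map recovers the
# two-fold oxidation contrast the generator encoded.
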