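import numpy as np
import pytest

from mitobulb import simgen


@pytest.fixture(scope="session")
def small_params():
    """A compact two-cell scene used by several recovery tests."""
    return simgen.SceneParams(n_cells=2, bulbs_per_cell=2, tubules_per_cell=4,
                              seed=3)


@pytest.fixture(scope="session")
def small_scene(small_params):
    return simgen.generate_scene(small_params, seed=3)


@pytest.fixture(scope="session")
def clean_egfp(small_scene):
    """Noise-free matrix-reporter render of the small scene."""
    return simgen.render_image(small_scene, channels=("egfp",),
                               noise=False, seed=0)["egfp"]


def gt_masks(scene, shape):
    """Ground-truth binary masks per organelle (pixel-center rasterization)."""
    from mitobulb.simgen import _rasterize
    return {o.organelle_id: _rasterize(o.polygon, shape,
                                       scene.params.pixel_size)
            for o in scene.organelles}


def best_jaccard(mask, labels):
    """Best Jaccard overlap between a ground-truth mask and any label."""
    cand = np.unique(labels[mask])
    cand = cand[cand > 0]
    best = 0.0
    for lab in cand:
        lm = labels == lab
        best = max(best, (lm & mask).sum() / (lm | mask).sum())
    return best
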