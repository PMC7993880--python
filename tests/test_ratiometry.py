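"""Trace extraction, half-max AUC integration, ratio comparison and the
roGFP2 ratio map."""

import numpy as np
import pytest
from scipy.special import erf

from mitobulb import ratiometry as rt
from mitobulb import simgen


# ------------------------------------------------------------- extraction

def test_constant_images_give_constant_traces():
    a, b = np.full((50, 50), 4.0), np.full((50, 50), 2.0)
    tr = rt.extract_trace(a, b, (0.3, 0.3), (2.0, 2.0), pixel_size=0.06)
    np.testing.assert_allclose(tr.channel_a, 4.0)
    np.testing.assert_allclose(tr.channel_b, 2.0)


def test_axis_aligned_trace_reproduces_pixel_row():
    img = np.arange(100.0).reshape(10, 10)
    tr = rt.extract_trace(img, img, (0.0, 3.0), (9.0, 3.0), pixel_size=1.0,
                          spacing_um=1.0)
    np.testing.assert_allclose(tr.channel_a, img[3, :])


def test_trace_across_gaussian_ridge_recovers_width():
    sigma_um = 0.3
    ps = 0.06
    yy, xx = np.mgrid[0:100, 0:100] * ps
    ridge = 100 * np.exp(-((yy - 3.0) ** 2) / (2 * sigma_um**2))
    tr = rt.extract_trace(ridge, ridge, (3.0, 0.5), (3.0, 5.5), ps)
    xs = np.arange(len(tr.channel_a)) * tr.sample_spacing
    prof = tr.channel_a
    mu = (xs * prof).sum() / prof.sum()
    sd = np.sqrt(((xs - mu) ** 2 * prof).sum() / prof.sum())
    assert sd == pytest.approx(sigma_um, rel=0.05)


def test_endpoints_outside_image_rejected():
    img = np.zeros((20, 20))
    with pytest.raises(ValueError):
        rt.extract_trace(img, img, (0, 0), (5.0, 5.0), pixel_size=0.06)


# ----------------------------------------------------------- half-max AUC

def test_triangular_peak_auc():
    """Symmetric triangle height 10, base 4 um: AUC between half-max = 15."""
    spacing = 0.01
    x = np.arange(0, 6 + spacing, spacing)
    prof = np.clip(10 - 5 * np.abs(x - 3.0), 0, None)
    res = rt.halfmax_auc(prof, background_level=0.0, spacing=spacing)
    assert res.valid and not res.truncated
    assert res.auc == pytest.approx(15.0, rel=1e-3)


@pytest.mark.parametrize("amp,sigma_samples", [(10.0, 5.0), (3.0, 12.0)])
def test_gaussian_peak_closed_form(amp, sigma_samples):
    """AUC between half-max of a Gaussian = A sigma sqrt(2 pi) erf(sqrt(ln 2))."""
    n = int(20 * sigma_samples)
    x = np.arange(n, dtype=float)
    prof = amp * np.exp(-((x - n / 2) ** 2) / (2 * sigma_samples**2))
    res = rt.halfmax_auc(prof)
    expected = amp * sigma_samples * np.sqrt(2 * np.pi) * erf(np.sqrt(np.log(2)))
    assert res.auc == pytest.approx(expected, rel=0.01)


def test_degenerate_profiles_flagged():
    assert not rt.halfmax_auc(np.zeros(10)).valid
    assert not rt.halfmax_auc(np.full(10, 3.0), background_level=5.0).valid
    # peak at the trace edge: window truncated
    res = rt.halfmax_auc(np.array([10.0, 8.0, 4.0, 1.0, 0.0]))
    assert res.valid and res.truncated


def test_auc_positively_homogeneous():
    rng = np.random.default_rng(0)
    prof = np.convolve(rng.uniform(0, 1, 80), np.ones(8) / 8, "same") + \
        np.exp(-((np.arange(80) - 40.0) ** 2) / 50)
    base = rt.halfmax_auc(prof).auc
    for k in (0.5, 3.0, 17.0):
        assert rt.halfmax_auc(k * prof).auc == pytest.approx(k * base, rel=1e-12)


# ------------------------------------------------------- ratio comparison

def _synthetic_traces(bulb_scale=0.8, n_cells=3, rng=None):
    rng = rng or np.random.default_rng(0)
    traces = []
    x = np.arange(51.0)
    for c in range(n_cells):
        base = rng.uniform(80, 120)
        for j, cls in enumerate(["bulb", "bulb", "tubular", "tubular"]):
            prof_b = base * np.exp(-((x - 25) ** 2) / (2 * 6.0**2))
            scale = bulb_scale if cls == "bulb" else 1.0
            prof_a = scale * prof_b
            traces.append(rt.LineTrace(f"c{c}t{j}", f"cell{c}", cls,
                                       (0, 0), (5, 0), 0.1, prof_a, prof_b,
                                       image_id="img0"))
    return traces


def test_uniform_bulb_scaling_gives_exact_reduction():
    tq = rt.trace_ratio_comparison(_synthetic_traces(bulb_scale=0.8))
    assert tq.relative_reduction_percent == pytest.approx(20.0, abs=1e-9)
    assert tq.welch.p_value < 0.01 or tq.welch.degenerate


def test_reduction_invariant_to_global_channel_gain():
    base = _synthetic_traces(bulb_scale=0.75)
    tq0 = rt.trace_ratio_comparison(base)
    for k in (0.2, 7.0):
        scaled = [rt.LineTrace(t.trace_id, t.cell_id, t.cls, t.p0, t.p1,
                               t.sample_spacing, k * t.channel_a, t.channel_b,
                               image_id=t.image_id) for t in base]
        tq = rt.trace_ratio_comparison(scaled)
        assert tq.relative_reduction_percent == pytest.approx(
            tq0.relative_reduction_percent, abs=1e-9)


def test_cell_missing_one_class_excluded():
    traces = _synthetic_traces()
    lone = rt.LineTrace("solo", "cellX", "bulb", (0, 0), (5, 0), 0.1,
                        traces[0].channel_a, traces[0].channel_b,
                        image_id="img0")
    tq = rt.trace_ratio_comparison(traces + [lone])
    assert any("cellX" in e[0] for e in tq.excluded)
    assert tq.n_cells == 3


def test_ratio_floor_excludes_depolarized_traces():
    traces = _synthetic_traces(bulb_scale=0.8)
    dead = rt.LineTrace("dead", "cell0", "bulb", (0, 0), (5, 0), 0.1,
                        0.01 * traces[0].channel_b, traces[0].channel_b,
                        image_id="img0")
    tq = rt.trace_ratio_comparison(traces + [dead], ratio_floor=0.1)
    assert any(e[0] == "dead" for e in tq.excluded)
    assert tq.relative_reduction_percent == pytest.approx(20.0, abs=1e-9)


def test_recovery_from_rendered_scene():
    p = simgen.SceneParams(n_cells=1, bulbs_per_cell=2, tubules_per_cell=4,
                           seed=5)
    s = simgen.generate_scene(p, seed=5)
    chans = simgen.render_image(s, channels=("egfp", "tmrm"), noise=True,
                                seed=11)
    rows = simgen.plan_traces(s, seed=2)
    traces = [rt.extract_trace(chans["tmrm"], chans["egfp"],
                               (r["x0_um"], r["y0_um"]), (r["x1_um"], r["y1_um"]),
                               p.pixel_size, trace_id=r["trace_id"],
                               cell_id=r["cell_id"], cls=r["class"],
                               image_id="i0") for r in rows]
    tq = rt.trace_ratio_comparison(traces)
    assert tq.relative_reduction_percent == pytest.approx(20.0, abs=8.0)


# --------------------------------------------------------------- ratio map

def test_ratio_map_identity_and_floor():
    rng = np.random.default_rng(1)
    img = rng.uniform(1, 10, (40, 40))
    rm = rt.ratio_map(img, img)
    np.testing.assert_allclose(rm.ratio[rm.valid_mask], 1.0)
    low = img.copy()
    low[5, 5] = 0.5
    rm2 = rt.ratio_map(img, low, intensity_floor=0.9)
    assert not rm2.valid_mask[5, 5]
    assert np.isnan(rm2.ratio[5, 5])


def test_ratio_map_recovers_organelle_contrast():
    p = simgen.SceneParams(n_cells=1, bulbs_per_cell=2, tubules_per_cell=3,
                           seed=8)
    s = simgen.generate_scene(p, seed=8)
    chans = simgen.render_image(s, channels=("rogfp405", "rogfp488"),
                                noise=True, seed=2)
    from mitobulb.simgen import _rasterize
    shape = chans["rogfp405"].shape
    labels = np.zeros(shape, np.int32)
    for o in s.organelles:
        labels[_rasterize(o.polygon.buffer(-0.1), shape, p.pixel_size)] = \
            o.organelle_id
    rm = rt.ratio_map(chans["rogfp405"], chans["rogfp488"],
                      mito_mask=labels > 0,
                      intensity_floor=3 * p.background_level,
                      labels=labels)
    for o in s.organelles:
        med = rm.organelle_medians[o.organelle_id]
        assert med == pytest.approx(o.ox_ratio, rel=0.10)
    bulb_meds = [rm.organelle_medians[o.organelle_id] for o in s.bulbs()]
    tub_meds = [rm.organelle_medians[o.organelle_id] for o in s.tubules()]
    assert np.mean(bulb_meds) / np.mean(tub_meds) == pytest.approx(2.0, rel=0.10)
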