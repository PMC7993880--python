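"""Density filtering, clustering and shape metrics against brute-force
oracles and an independent DBSCAN implementation."""

import numpy as np
import pandas as pd
import pytest

from mitobulb import simgen
from mitobulb import storm_shapes as st
from mitobulb.geometry import CollinearPointsError


def _locs(xy):
    xy = np.asarray(xy, float)
    return pd.DataFrame({"id": np.arange(1, len(xy) + 1),
                         "x_nm": xy[:, 0], "y_nm": xy[:, 1],
                         "z_nm": 0.0, "photons": 1500.0,
                         "frame": np.arange(1, len(xy) + 1)})


# ------------------------------------------------------------ density filter

def test_isolated_point_removed_and_coincident_points_kept():
    lone = _locs([[0, 0]])
    assert len(st.density_filter(lone, 70, 10)) == 0
    ten = _locs([[5, 5]] * 10)  # neighbor count includes the point itself
    assert len(st.density_filter(ten, 70, 10)) == 10


def test_density_filter_matches_bruteforce():
    rng = np.random.default_rng(3)
    xy = rng.uniform(0, 2000, size=(500, 2))
    locs = _locs(xy)
    out = st.density_filter(locs, 70, 3)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    keep = (d2 <= 70.0**2).sum(axis=1) >= 3  # includes self (d=0)
    np.testing.assert_array_equal(out["id"].to_numpy(),
                                  locs.loc[keep, "id"].to_numpy())


def test_density_filter_output_subset_single_pass():
    rng = np.random.default_rng(4)
    core = rng.normal(0, 20, size=(30, 2))
    halo = rng.normal(0, 300, size=(40, 2))
    locs = _locs(np.vstack([core, halo]))
    once = st.density_filter(locs, 70, 10)
    assert set(once["id"]) <= set(locs["id"])
    # single-pass semantics: re-filtering the output may remove more points
    twice = st.density_filter(once, 70, 10)
    assert len(twice) <= len(once)


# ---------------------------------------------------------------- clustering

def dbscan_bruteforce(xy, eps, min_pts):
    """O(n^2) reference with the same semantics as cluster_localizations."""
    n = len(xy)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    within = d2 <= eps**2
    core = within.sum(axis=1) >= min_pts
    labels = np.zeros(n, int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i]:
            continue
        cluster += 1
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(within[j] & core):
                if not labels[k]:
                    labels[k] = cluster
                    stack.append(k)
    for i in np.flatnonzero(~core):
        cand = np.flatnonzero(core & within[i])
        if len(cand):
            best = cand[np.lexsort((cand, d2[i, cand]))[0]]
            labels[i] = labels[best]
    return labels


def test_two_separated_blobs_two_clusters():
    rng = np.random.default_rng(0)
    a = rng.normal([0, 0], 30, size=(100, 2))
    b = rng.normal([1000, 0], 30, size=(100, 2))
    labels = st.cluster_localizations(_locs(np.vstack([a, b])), 70, 10)
    assert labels.max() == 2
    assert len(set(labels[:100])) == 1 and len(set(labels[100:])) == 1


def test_close_blobs_bridge_into_one_cluster():
    rng = np.random.default_rng(1)
    a = rng.normal([0, 0], 50, size=(150, 2))
    b = rng.normal([100, 0], 50, size=(150, 2))
    labels = st.cluster_localizations(_locs(np.vstack([a, b])), 70, 10)
    assert labels.max() == 1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_clustering_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    blobs = [rng.normal(c, 40, size=(60, 2))
             for c in ([0, 0], [400, 100], [150, 600])]
    noise = rng.uniform(-300, 900, size=(80, 2))
    xy = np.vstack(blobs + [noise])
    labels = st.cluster_localizations(_locs(xy), 70, 10)
    np.testing.assert_array_equal(labels, dbscan_bruteforce(xy, 70, 10))


def test_clustering_core_labels_match_sklearn():
    """Independent cross-check: core-point partition agrees with sklearn."""
    from sklearn.cluster import DBSCAN

    rng = np.random.default_rng(7)
    xy = np.vstack([rng.normal(c, 35, size=(80, 2))
                    for c in ([0, 0], [500, 0], [250, 450])])
    labels = st.cluster_localizations(_locs(xy), 70, 10)
    sk = DBSCAN(eps=70, min_samples=10).fit(xy)
    core = np.zeros(len(xy), bool)
    core[sk.core_sample_indices_] = True
    # same partition of core points (label names may differ)
    mapping = {}
    for ours, theirs in zip(labels[core], sk.labels_[core]):
        assert mapping.setdefault(ours, theirs) == theirs
    assert len(set(mapping.values())) == len(mapping)


def test_cluster_count_recovery_over_seeds():
    hits = 0
    for seed in range(10):
        locs, truth = simgen.generate_localizations(
            simgen.StormParams(seed=seed), n_nucleoids=12, seed=seed)
        filt = st.density_filter(locs)
        labels = st.cluster_localizations(filt)
        hits += labels.max() == len(truth)
    assert hits >= 10 * 0.95


# ------------------------------------------------------------- shape metrics

def test_circle_and_ellipse_shapes():
    th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    circ = 75 * np.stack([np.cos(th), np.sin(th)], 1)
    s = st.shape_metrics(circ)
    assert s.semi_diameter == pytest.approx(75, rel=0.01)
    assert s.ellipticity == pytest.approx(1.0, abs=0.01)
    ell = np.stack([90 * np.cos(th), 60 * np.sin(th)], 1)
    s = st.shape_metrics(ell)
    assert s.d_min == pytest.approx(120, rel=0.01)
    assert s.d_max == pytest.approx(180, rel=0.01)
    assert s.semi_diameter == pytest.approx(75, rel=0.01)
    assert s.ellipticity == pytest.approx(1.5, rel=0.01)


def test_square_ellipticity_unity():
    sq = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], float)
    s = st.shape_metrics(sq)
    # 4-fold symmetry: max feret is the diagonal, min the side
    assert s.ellipticity == pytest.approx(np.sqrt(2), rel=1e-6)
    th = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
    circle = np.stack([np.cos(th), np.sin(th)], 1)
    assert st.shape_metrics(circle).ellipticity == pytest.approx(1, abs=1e-3)


def test_moment_method_inverts_localization_blur():
    rng = np.random.default_rng(2)
    a, b, sigma = 90.0, 60.0, 13.0
    th = rng.uniform(0, 2 * np.pi, 3000)
    r = np.sqrt(rng.uniform(0, 1, 3000))
    pts = np.stack([a * r * np.cos(th), b * r * np.sin(th)], 1)
    jittered = pts + rng.normal(0, sigma, pts.shape)
    s = st.shape_metrics(jittered, method="moment",
                         localization_precision=sigma)
    assert s.d_max == pytest.approx(2 * a, rel=0.05)
    assert s.d_min == pytest.approx(2 * b, rel=0.05)
    # the uncorrected hull overestimates the true extent
    s_hull = st.shape_metrics(jittered, method="feret")
    assert s_hull.d_max > 2 * a


def test_degenerate_clusters_skipped_with_reason():
    line = np.stack([np.arange(20.0), np.arange(20.0)], 1)
    locs = _locs(np.vstack([line, np.random.default_rng(0)
                            .normal(500, 30, (50, 2))]))
    labels = np.array([1] * 20 + [2] * 50)
    summ = st.measure_clusters(locs, labels)
    assert summ.skipped and summ.skipped[0][0] == 1
    assert summ.n_clusters == 1
    with pytest.raises(CollinearPointsError):
        st.shape_metrics(np.array([[0.0, 0.0], [1.0, 1.0]]))


def test_border_clusters_flagged_and_excluded_from_summary():
    rng = np.random.default_rng(5)
    inner = rng.normal([500, 500], 30, (60, 2))
    edge = rng.normal([30, 500], 30, (60, 2))
    locs = _locs(np.vstack([inner, edge]))
    labels = np.array([1] * 60 + [2] * 60)
    summ = st.measure_clusters(locs, labels, field_bounds=(0, 0, 1000, 1000))
    flags = {s.cluster_id: s.border_flag for s in summ.shapes}
    assert not flags[1] and flags[2]
    assert summ.n_clusters == 1


def test_population_recovery_of_generating_mean():
    locs, truth = simgen.generate_localizations(
        simgen.StormParams(seed=7), n_nucleoids=24, seed=7)
    filt = st.density_filter(locs)
    labels = st.cluster_localizations(filt)
    summ = st.measure_clusters(filt, labels, method="moment",
                               localization_precision=13.0)
    assert summ.n_clusters >= 22
    se = 19.6 / np.sqrt(summ.n_clusters)
    assert abs(summ.mean_semi_diameter - 75.3) <= 2 * se
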