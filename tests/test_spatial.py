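"""Spatial statistics: distance fields, annulus profiles, per-axon metrics,
colocalization and dystrophy association — with brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from periplaque import (
    AnnulusBinSpec,
    PixelCalibration,
    annulus_profile,
    axon_closest_approach,
    coloc_fraction,
    distance_field,
    dn_per_plaque,
    linear_density,
    nnd3,
    subject_linear_density,
)
from periplaque.spatial import (
    AxonTrace,
    annulus_profile_exact,
    depletion_radius_estimate,
)

from conftest import disk


def _puncta(xy):
    xy = np.atleast_2d(xy)
    return pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1]})


# ---------------------------------------------------------------------------
# distance field


def test_distance_field_matches_analytic_disk(calib_02):
    R = 10.0
    dfield = distance_field([disk(50, 50, R)], calib_02)
    yy, xx = np.mgrid[0:500, 0:500]
    x_um = (xx + 0.5) * 0.2
    y_um = (yy + 0.5) * 0.2
    analytic = np.hypot(x_um - 50, y_um - 50) - R
    assert np.abs(dfield - analytic).max() < 1.5 * 0.2  # within ~1 px


def test_distance_field_two_disks_is_pointwise_min(calib_02):
    d1 = distance_field([disk(30, 40, 6)], calib_02)
    d2 = distance_field([disk(70, 60, 9)], calib_02)
    both = distance_field([disk(30, 40, 6), disk(70, 60, 9)], calib_02)
    np.testing.assert_allclose(both, np.minimum(d1, d2), atol=0.3)


def test_distance_field_without_plaques_is_infinite(calib_02):
    dfield = distance_field([], calib_02)
    assert np.isinf(dfield).all()


# ---------------------------------------------------------------------------
# annulus profile


def test_annulus_classification_hand_placed(calib_02):
    """Disk R=5 at the centre of a 100x100 um ROI; boutons inside, at 2 um
    and at 20 um fall in (interior, 0-5, 15-25)."""
    dfield = distance_field([disk(50, 50, 5)], calib_02)
    boutons = _puncta([[50, 50], [50, 50 - 7], [50, 50 + 25]])
    prof = annulus_profile(boutons, dfield, calib_02)
    assert prof["bouton_count"].tolist() == [1, 1, 0, 1, 0]


def test_percentages_sum_to_100(small_null_scene, calib_02):
    dfield = distance_field(small_null_scene.plaque_polygons, calib_02)
    prof = annulus_profile(small_null_scene.kept_boutons, dfield, calib_02)
    assert prof["percentage"].sum() == pytest.approx(100.0, abs=1e-9)


def test_empty_bouton_set_reports_missing(calib_02):
    dfield = distance_field([disk(50, 50, 5)], calib_02)
    prof = annulus_profile(_puncta(np.empty((0, 2))), dfield, calib_02)
    assert (prof["bouton_count"] == 0).all()
    assert prof["percentage"].isna().all()


def test_uniform_boutons_give_flat_percentages():
    """CSR boutons around an interior disk plaque: every bin's mean
    percentage is ~100/5 (Monte Carlo, 3-SE band per bin)."""
    calib = PixelCalibration(0.4, 0.4, 500, 500)  # 200x200 um
    poly = disk(100, 100, 10)
    dfield = distance_field([poly], calib)
    rng = np.random.default_rng(0)
    pcts = []
    for _ in range(50):
        xy = rng.uniform(0, 200, size=(4000, 2))
        prof = annulus_profile(_puncta(xy), dfield, calib)
        pcts.append(prof["percentage"].to_numpy())
    pcts = np.asarray(pcts)
    mean = pcts.mean(axis=0)
    se = pcts.std(axis=0, ddof=1) / np.sqrt(len(pcts))
    assert np.all(np.abs(mean - 20.0) < 3.0 * se + 1e-9)


def test_annulus_disk_ring_areas_match_closed_form():
    """For a disk plaque fully in the ROI, pixel-counted bin areas match
    pi*((R+e2)^2 - (R+e1)^2) within 2% at 0.2 um/px."""
    R = 10.0
    calib = PixelCalibration(0.2, 0.2, 1000, 1000)  # 200x200 um
    dfield = distance_field([disk(100, 100, R)], calib)
    prof = annulus_profile(_puncta(np.empty((0, 2))), dfield, calib)
    edges = [0.0, 5.0, 15.0, 25.0, 35.0]
    analytic = [np.pi * R**2] + [
        np.pi * ((R + b) ** 2 - (R + a) ** 2) for a, b in zip(edges[:-1], edges[1:])
    ]
    rel = np.abs(prof["area_um2"].to_numpy() - analytic) / analytic
    assert rel.max() < 0.02


def test_exact_profile_agrees_with_raster():
    calib = PixelCalibration(0.2, 0.2, 1000, 1000)
    polys = [disk(60, 60, 8), disk(140, 130, 6)]
    rng = np.random.default_rng(5)
    boutons = _puncta(rng.uniform(0, 200, size=(3000, 2)))
    dfield = distance_field(polys, calib)
    raster = annulus_profile(boutons, dfield, calib)
    exact = annulus_profile_exact(boutons, polys, (200.0, 200.0))
    np.testing.assert_allclose(
        raster["area_um2"], exact["area_um2"], rtol=0.03
    )
    assert np.abs(raster["percentage"] - exact["percentage"]).max() < 1.5


def test_zero_area_bin_excluded(calib_02, caplog):
    # plaque nearly filling the field: outer rings have no pixels
    dfield = distance_field([disk(50, 50, 48)], calib_02)
    prof = annulus_profile(_puncta([[50, 50]]), dfield, calib_02)
    assert (prof.loc[prof["area_um2"] == 0, "percentage"].isna()).all()
    defined = prof["percentage"].dropna()
    assert defined.sum() == pytest.approx(100.0)


def test_depletion_radius_estimate_synthetic_profile():
    bins = AnnulusBinSpec()
    prof = pd.DataFrame(
        {
            "bin_label": bins.labels,
            "density_per_um2": [0.01, 0.012, 0.05, 0.051, 0.05],
        }
    )
    assert depletion_radius_estimate(prof, bins) == 5.0


# ---------------------------------------------------------------------------
# per-axon


def test_closest_approach_geometry(calib_02):
    dfield = distance_field([disk(50, 50, 10)], calib_02)
    tangent = AxonTrace(0, np.array([[5.0, 37.0], [95.0, 37.0]]))  # 3 um gap
    d, label = axon_closest_approach(tangent, dfield, calib_02)
    assert d == pytest.approx(3.0, abs=0.3)
    assert label == "0-5 um"
    crossing = AxonTrace(1, np.array([[5.0, 50.0], [95.0, 50.0]]))
    d, label = axon_closest_approach(crossing, dfield, calib_02)
    assert d < 0 and label == "0-5 um"
    # brute-force min over the resampled points
    arc, xy = crossing.resample(0.2)
    jj = np.clip(np.round(xy[:, 0] / 0.2 - 0.5).astype(int), 0, 499)
    ii = np.clip(np.round(xy[:, 1] / 0.2 - 0.5).astype(int), 0, 499)
    assert d == pytest.approx(dfield[ii, jj].min())


def test_far_axon_excluded(calib_02):
    dfield = distance_field([disk(10, 10, 3)], calib_02)
    far = AxonTrace(0, np.array([[90.0, 90.0], [95.0, 95.0]]))
    d, label = axon_closest_approach(far, dfield, calib_02)
    assert d > 35.0 and label is None


def test_nnd3_hand_computation():
    res = nnd3(np.array([0.0, 10.0, 20.0, 30.0]))
    assert res is not None
    per_bouton, mean = res
    np.testing.assert_allclose(per_bouton, [20.0, 40.0 / 3, 40.0 / 3, 20.0])
    assert mean == pytest.approx(50.0 / 3)


def test_nnd3_requires_four_boutons():
    assert nnd3(np.array([0.0, 5.0, 9.0])) is None


def _nnd3_bruteforce(arc, k=3):
    arc = np.asarray(arc, dtype=float)
    out = []
    for i in range(len(arc)):
        d = sorted(abs(arc[i] - arc[j]) for j in range(len(arc)) if j != i)
        out.append(sum(d[:k]) / k)
    return np.asarray(out)


def test_nnd3_matches_bruteforce_oracle():
    rng = np.random.default_rng(12)
    for _ in range(500):
        n = rng.integers(4, 40)
        arc = rng.uniform(0, 200, size=n)
        per_bouton, mean = nnd3(arc)
        oracle = _nnd3_bruteforce(arc)
        np.testing.assert_allclose(per_bouton, oracle, rtol=0, atol=1e-12)
        assert mean == pytest.approx(oracle.mean())


def test_nnd3_duplicate_positions_allowed():
    per_bouton, _ = nnd3(np.array([0.0, 0.0, 5.0, 9.0]))
    assert per_bouton[0] > 0  # duplicates contribute distance 0 but are legal
    assert np.isfinite(per_bouton).all()


def test_nnd3_deletion_monotonicity():
    """Removing a bouton never decreases any other bouton's NND-3."""
    rng = np.random.default_rng(3)
    for _ in range(50):
        arc = rng.uniform(0, 100, size=10)
        full, _ = nnd3(arc)
        drop = rng.integers(0, 10)
        reduced, _ = nnd3(np.delete(arc, drop))
        kept_full = np.delete(full, drop)
        assert np.all(reduced >= kept_full - 1e-12)


def test_nnd3_reparameterization_invariance():
    verts = np.array([[0.0, 0.0], [30.0, 5.0], [60.0, 0.0], [100.0, 10.0]])
    ax = AxonTrace(0, verts)
    # insert midpoints along the same path
    dense = []
    for a, b in zip(verts[:-1], verts[1:]):
        dense.extend([a, (a + b) / 2])
    dense.append(verts[-1])
    ax2 = AxonTrace(0, np.asarray(dense))
    xy = ax.point_at(np.array([3.0, 20.0, 55.0, 80.0, 95.0]))
    _, arc1 = ax.project(xy)
    _, arc2 = ax2.project(xy)
    r1 = nnd3(arc1)
    r2 = nnd3(arc2)
    np.testing.assert_allclose(r1[0], r2[0], atol=1e-9)


def test_geodesic_at_least_euclidean():
    rng = np.random.default_rng(8)
    verts = np.cumsum(rng.normal(0, 2, size=(40, 2)), axis=0) + 50
    ax = AxonTrace(0, verts)
    arcs = np.sort(rng.uniform(0, ax.total_length_um, size=10))
    xy = ax.point_at(arcs)
    geo = np.abs(arcs[:, None] - arcs[None, :])
    euc = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
    assert np.all(geo >= euc - 1e-9)


def test_linear_density_and_subject_rule():
    assert linear_density(500.0, 25) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        linear_density(0.0, 3)
    table = pd.DataFrame(
        {
            "subject_id": ["a", "a", "b"],
            "total_length_um": [600.0, 500.0, 900.0],
            "n_boutons": [30, 25, 45],
        }
    )
    out = subject_linear_density(table).set_index("subject_id")
    assert bool(out.loc["a", "included"])  # 1100 um > 1000
    assert not bool(out.loc["b", "included"])  # 900 um fails the rule
    assert out.loc["a", "density_per_100um"] == pytest.approx(55 / 11)


def test_subject_density_matches_renewal_expectation():
    """No depletion, 10 um mean spacing: subject density ~10 per 100 um."""
    from periplaque import SceneConfig, sample_scene
    from periplaque.spatial import axon_metrics_table

    dens = []
    for seed in range(30):
        cfg = SceneConfig(
            field_size_um=(200.0, 200.0), n_plaques=0, n_axons=10,
            mean_inter_bouton_um=10.0, axon_rate_cv=0.0,
            depletion_prob_inside=0.0, depletion_prob_ring=0.0,
            dystrophy_prob_per_plaque_axon=0.0, seed=seed,
        )
        scene = sample_scene(cfg)
        total_len = sum(ax.total_length_um for ax in scene.axons)
        dens.append(100.0 * len(scene.boutons) / total_len)
    dens = np.asarray(dens)
    se = dens.std(ddof=1) / np.sqrt(len(dens))
    assert abs(dens.mean() - 10.0) < 3.0 * se


# ---------------------------------------------------------------------------
# colocalization / dystrophies


def test_coloc_identical_sets_is_100():
    xy = np.random.default_rng(1).uniform(0, 50, size=(40, 2))
    frac, pairs = coloc_fraction(xy, xy.copy(), max_dist_um=0.5)
    assert frac == 100.0
    assert len(pairs) == 40


def test_coloc_empty_post_is_0_and_empty_pre_is_nan():
    xy = np.array([[1.0, 1.0], [2.0, 2.0]])
    frac, _ = coloc_fraction(xy, np.empty((0, 2)), 0.5)
    assert frac == 0.0
    frac, _ = coloc_fraction(np.empty((0, 2)), xy, 0.5)
    assert np.isnan(frac)


def test_coloc_greedy_matching_is_one_to_one():
    pre = np.array([[0.0, 0.0], [0.3, 0.0]])
    post = np.array([[0.1, 0.0]])  # one post between two pre
    frac, pairs = coloc_fraction(pre, post, 0.5)
    assert frac == 50.0
    assert pairs.tolist() == [[0, 0]]  # nearer pre wins


def test_dn_per_plaque_edge_cases():
    polys = [disk(20, 20, 5), disk(60, 60, 5)]
    frac, _ = dn_per_plaque(polys, np.empty((0, 2)))
    assert frac == 0.0
    frac, table = dn_per_plaque(polys, np.array([[20, 20], [60, 60]]))
    assert frac == 100.0
    assert (table["n_dystrophies"] == 1).all()
    frac, _ = dn_per_plaque([], np.array([[1.0, 1.0]]))
    assert np.isnan(frac)


def test_dn_association_radius():
    polys = [disk(20, 20, 5)]
    frac, _ = dn_per_plaque(polys, np.array([[20.0, 29.0]]), association_radius_um=5.0)
    assert frac == 100.0  # 4 um from the boundary
    frac, _ = dn_per_plaque(polys, np.array([[20.0, 31.0]]), association_radius_um=5.0)
    assert frac == 0.0  # 6 um from the boundary
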