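"""Synthetic orchard generator: determinism, geometry, truth consistency."""

import numpy as np
import pytest

from orchardpheno.cloud import (LABEL_FLOWER, LABEL_GROUND, LABEL_PANEL)
from orchardpheno.synthetic import (SceneConfig, generate_scene,
                                    generate_time_series)

from conftest import noise_free_config


def test_same_config_and_seed_is_bitwise_identical():
    cfg = SceneConfig(seed=3, n_rows=2, n_cols=3)
    c1, t1 = generate_scene(cfg)
    c2, t2 = generate_scene(cfg)
    for col in ("x", "y", "z", "r", "g", "b"):
        np.testing.assert_array_equal(getattr(c1, col), getattr(c2, col))
    assert t1.trees.equals(t2.trees)


def test_zero_flower_density_means_no_flower_points():
    cfg = noise_free_config(n_rows=2, n_cols=3, flower_density=0.0)
    cloud, truth = generate_scene(cfg)
    assert (truth.trees["true_flower_count"] == 0).all()
    assert not np.any(cloud.class_label == LABEL_FLOWER)


def test_ten_percent_slope_drops_one_metre_over_ten():
    cfg = noise_free_config(slope=0.10)
    z0 = cfg.ground_elevation(0.0, 5.0)
    z1 = cfg.ground_elevation(10.0, 5.0)
    assert z1 - z0 == pytest.approx(1.0)
    cloud, _ = generate_scene(cfg)
    ground = cloud.subset(cloud.class_label == LABEL_GROUND)
    # empirical: regression of ground z on x recovers the 10% gradient
    slope = np.polyfit(ground.x, ground.z, 1)[0]
    assert slope == pytest.approx(0.10, abs=1e-3)


def test_panel_brightness_matches_reflectance_and_ordering(default_scene):
    cloud, truth = default_scene
    brightness = (cloud.r + cloud.g + cloud.b) / 3.0
    means = {}
    for panel in truth.panels:
        x0, y0, x1, y1 = panel.footprint.bounds
        sel = ((cloud.class_label == LABEL_PANEL)
               & (cloud.x >= x0) & (cloud.x <= x1)
               & (cloud.y >= y0) & (cloud.y <= y1))
        means[panel.panel_id] = brightness[sel].mean()
        assert means[panel.panel_id] == pytest.approx(
            255.0 * panel.reflectance, abs=2.0)
    assert means["white"] > means["grey"] > means["black"]


def test_flower_points_bright_and_high(default_scene):
    cloud, truth = default_scene
    flowers = cloud.subset(cloud.class_label == LABEL_FLOWER)
    brightness = (flowers.r + flowers.g + flowers.b) / 3.0
    grey_nominal = 255.0 * 0.43
    assert brightness.min() > grey_nominal
    # height above the local terrain plane exceeds the 1 m flower floor
    ground_z = 100.0 + 0.0 * flowers.x
    assert np.all(flowers.z - ground_z > 1.0)


def test_flower_count_equals_density_times_volume():
    cfg = noise_free_config(n_rows=2, n_cols=3, flower_density=20.0)
    _, truth = generate_scene(cfg)
    expected = np.round(20.0 * truth.trees["true_volume"]).astype(int)
    np.testing.assert_array_equal(truth.trees["true_flower_count"], expected)


def test_true_volume_is_analytic_half_ellipsoid():
    cfg = noise_free_config(n_rows=2, n_cols=3)
    _, truth = generate_scene(cfg)
    t = truth.trees
    expected = (2.0 / 3.0) * np.pi * t["a"] * t["b"] * t["c"]
    np.testing.assert_allclose(t["true_volume"], expected, rtol=1e-12)
    np.testing.assert_allclose(t["true_height"],
                               t["c"] + cfg.crown_base_height, rtol=1e-12)


def test_missing_trees_are_absent():
    cfg = noise_free_config(n_rows=2, n_cols=3, missing_tree_ids=(2,))
    cloud, truth = generate_scene(cfg)
    assert 2 not in truth.trees["tree_id"].values
    assert len(truth.trees) == 5
    # no canopy points near the missing trunk
    missing_x, missing_y = 4.0 + 2 * 6.0, 4.0
    near = (np.hypot(cloud.x - missing_x, cloud.y - missing_y) < 1.0) & (
        cloud.z > 101.0)
    assert not near.any()


def test_degenerate_grid_is_an_error():
    with pytest.raises(ValueError):
        SceneConfig(n_rows=0, n_cols=5)


def test_time_series_counts_follow_profile():
    cfg = noise_free_config(n_rows=2, n_cols=3)
    dates = [1, 2, 3, 4, 5]
    profile = {v: [0.0, 8.0, 20.0, 6.0, 1.0] for v in cfg.varieties}
    series = generate_time_series(cfg, dates, profile)
    assert [d for d, _, _ in series] == dates
    counts = np.array([t.trees["true_flower_count"].to_numpy()
                       for _, _, t in series])
    # per-tree counts peak on the peak date of the profile
    assert (counts.argmax(axis=0) == 2).all()
    vols = series[0][2].trees["true_volume"].to_numpy()
    np.testing.assert_array_equal(counts[1], np.round(8.0 * vols))
    # crown geometry identical across dates
    t0, t4 = series[0][2].trees, series[4][2].trees
    np.testing.assert_array_equal(t0["true_height"], t4["true_height"])


def test_time_series_profile_arithmetic_oracle():
    """A 20 flowers/m3 profile on a 9.4 m3 crown yields round(188) flowers."""
    assert int(round(20.0 * 9.4)) == 188
    cfg = noise_free_config(n_rows=1, n_cols=1)
    series = generate_time_series(cfg, [1, 2], {cfg.varieties[0]: [20.0, 0.0]})
    _, _, truth = series[0]
    vol = truth.trees["true_volume"].iloc[0]
    assert truth.trees["true_flower_count"].iloc[0] == int(round(20.0 * vol))
    assert series[1][2].trees["true_flower_count"].iloc[0] == 0


def test_all_zero_profile_has_no_flowers():
    cfg = noise_free_config(n_rows=1, n_cols=2)
    series = generate_time_series(cfg, [1, 2], {cfg.varieties[0]: [0, 0],
                                                cfg.varieties[1]: [0, 0]})
    for _, cloud, truth in series:
        assert (truth.trees["true_flower_count"] == 0).all()
        assert not np.any(cloud.class_label == LABEL_FLOWER)


def test_negative_profile_is_an_error():
    cfg = noise_free_config(n_rows=1, n_cols=1)
    with pytest.raises(ValueError, match="non-negative"):
        generate_time_series(cfg, [1, 2], {cfg.varieties[0]: [1.0, -0.5]})


def test_non_increasing_dates_are_an_error():
    cfg = noise_free_config(n_rows=1, n_cols=1)
    with pytest.raises(ValueError, match="increasing"):
        generate_time_series(cfg, [2, 1], {cfg.varieties[0]: [0.0, 0.0]})
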