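"""Panel-calibrated flower detection and density computation."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from orchardpheno.cloud import LABEL_FLOWER, ColoredPointCloud
from orchardpheno.flowering import (FlowerThresholdClassifier,
                                    classify_flower_points,
                                    compute_brightness,
                                    flower_density_per_tree,
                                    panel_mean_brightness)
from orchardpheno.pipeline import process_date
from orchardpheno.synthetic import generate_scene

from conftest import noise_free_config


@pytest.mark.parametrize("rgb,expected", [
    ((255.0, 255.0, 255.0), 255.0),
    ((0.0, 0.0, 0.0), 0.0),
    ((30.0, 60.0, 90.0), 60.0),
])
def test_brightness_is_channel_mean(rgb, expected):
    cloud = ColoredPointCloud([0.0], [0.0], [0.0], [rgb[0]], [rgb[1]], [rgb[2]])
    assert compute_brightness(cloud).brightness[0] == expected


def test_panel_mean_brightness_arithmetic():
    n = 50
    rng = np.random.default_rng(0)
    cloud = ColoredPointCloud(rng.uniform(0, 1, n), rng.uniform(0, 1, n),
                              np.zeros(n), np.full(n, 110.0),
                              np.full(n, 110.0), np.full(n, 110.0))
    cloud = compute_brightness(cloud)
    ref = panel_mean_brightness(cloud, box(0, 0, 1, 1), "grey")
    assert ref.mean_brightness == pytest.approx(110.0)
    assert ref.n_points == n


def test_panel_with_no_points_is_an_error():
    cloud = compute_brightness(ColoredPointCloud([0.0], [0.0], [0.0],
                                                 [1.0], [1.0], [1.0]))
    with pytest.raises(ValueError, match="white"):
        panel_mean_brightness(cloud, box(10, 10, 11, 11), "white")


def test_synthetic_grey_panel_near_nominal(processed_default):
    result, _ = processed_default
    grey = result.panels["grey"]
    assert grey.mean_brightness == pytest.approx(255 * 0.43, abs=2.0)
    ordering = [result.panels[p].mean_brightness
                for p in ("white", "grey", "black")]
    assert ordering[0] > ordering[1] > ordering[2]


def test_classification_boundaries_inclusive_brightness_strict_height():
    """Brightness exactly at the threshold counts as flower; height exactly
    at or below 1 m does not."""
    zeros = np.zeros(3)
    cloud = ColoredPointCloud(
        [0, 1, 2], [0, 0, 0], [0, 0, 0], [110.0, 150.0, 150.0],
        [110.0, 150.0, 150.0], [110.0, 150.0, 150.0],
        height_above_ground=np.array([1.5, 0.9, 1.0]))
    cloud = compute_brightness(cloud)
    mask, labeled = classify_flower_points(cloud, threshold=110.0)
    assert mask.tolist() == [True, False, False]
    assert labeled.class_label[0] == LABEL_FLOWER


def test_raising_threshold_never_increases_counts(processed_default):
    result, _ = processed_default
    cloud = result.cloud
    counts = []
    for thr in (100.0, 140.0, 180.0, 220.0, 260.0):
        mask, _ = classify_flower_points(cloud, thr)
        counts.append(int(mask.sum()))
    assert counts == sorted(counts, reverse=True)
    assert counts[-1] == 0  # nothing is brighter than 255


def test_white_panel_yields_fewer_flowers_than_grey(processed_default):
    """White-panel thresholding classifies (far) fewer points as flowers."""
    result, truth = processed_default
    footprints = {p.panel_id: p.footprint for p in truth.panels}
    grey = FlowerThresholdClassifier(panel="grey").fit(result.cloud, footprints)
    white = FlowerThresholdClassifier(panel="white").fit(result.cloud, footprints)
    g = grey.predict(result.cloud)
    w = white.predict(result.cloud)
    assert w.sum() <= g.sum()
    assert np.all(w <= g)  # white flowers are a subset per point, so per tree


def test_illumination_rescaling_leaves_classification_unchanged(processed_default):
    result, truth = processed_default
    footprints = {p.panel_id: p.footprint for p in truth.panels}
    clf = FlowerThresholdClassifier(panel="grey")
    base = clf.fit(result.cloud, footprints).predict(result.cloud)
    dimmed = compute_brightness(result.cloud.scaled_colors(0.7))
    dimmed.height_above_ground = result.cloud.height_above_ground
    dim = clf.fit(dimmed, footprints).predict(dimmed)
    np.testing.assert_array_equal(dim, base)


def test_exact_flower_recovery_on_noise_free_scene():
    """With jitter off, grey-panel thresholding recovers exactly the
    generated flower points."""
    cfg = noise_free_config(n_rows=2, n_cols=3)
    cloud, truth = generate_scene(cfg)
    footprints = {p.panel_id: p.footprint for p in truth.panels}
    result = process_date(cloud, footprints, date="d0")
    est = result.flower_table.set_index("tree_id")["n_flower_points"]
    assert est.loc[-1] == 0  # no flower points outside crowns
    assert est.drop(-1).sum() == truth.trees["true_flower_count"].sum()
    n_flower_truth = int((cloud.class_label == LABEL_FLOWER).sum())
    mask = result.flower_mask
    assert int(mask.sum()) == n_flower_truth
    np.testing.assert_array_equal(
        np.sort(np.flatnonzero(mask)),
        np.flatnonzero(result.cloud.class_label == LABEL_FLOWER))


def test_density_arithmetic_and_zero_volume_flag():
    crowns = _single_square_crown()
    metrics = pd.DataFrame({"tree_id": [1], "crown_volume_m3": [25.0]})
    cloud, mask = _flower_points_inside(500)
    panel = _dummy_panel()
    table = flower_density_per_tree(cloud, mask, crowns, metrics, panel)
    row = table[table.tree_id == 1].iloc[0]
    assert row["n_flower_points"] == 500
    assert row["flower_density_per_m3"] == pytest.approx(20.0)
    metrics0 = pd.DataFrame({"tree_id": [1], "crown_volume_m3": [0.0]})
    table0 = flower_density_per_tree(cloud, mask, crowns, metrics0, panel)
    row0 = table0[table0.tree_id == 1].iloc[0]
    assert row0["n_flower_points"] == 500
    assert np.isnan(row0["flower_density_per_m3"])


def test_zero_flowers_gives_zero_density():
    crowns = _single_square_crown()
    metrics = pd.DataFrame({"tree_id": [1], "crown_volume_m3": [10.0]})
    cloud, mask = _flower_points_inside(10)
    mask = np.zeros_like(mask)
    table = flower_density_per_tree(cloud, mask, crowns, metrics,
                                    _dummy_panel())
    assert table[table.tree_id == 1]["flower_density_per_m3"].iloc[0] == 0.0


def _single_square_crown():
    from orchardpheno.segmentation import Crown, CrownMap
    poly = box(0, 0, 4, 4)
    crown = Crown(crown_id=1, polygon=poly, centroid=(2.0, 2.0),
                  point_indices=np.arange(0))
    label = np.ones((16, 16), dtype=np.int32)
    return CrownMap(crowns=[crown], label_image=label, x0=0.0, y0=0.0,
                    cell_size=0.25)


def _flower_points_inside(n):
    rng = np.random.default_rng(1)
    cloud = ColoredPointCloud(rng.uniform(0.1, 3.9, n),
                              rng.uniform(0.1, 3.9, n),
                              np.full(n, 2.0), np.full(n, 220.0),
                              np.full(n, 220.0), np.full(n, 220.0),
                              height_above_ground=np.full(n, 2.0))
    return compute_brightness(cloud), np.ones(n, dtype=bool)


def _dummy_panel():
    from orchardpheno.flowering import PanelReference
    return PanelReference(panel_id="grey", footprint=box(10, 10, 11, 11),
                          reflectance=0.43, mean_brightness=109.65,
                          n_points=100)
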