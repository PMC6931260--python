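"""Synthetic orchard scenes with exact ground truth.

Emulates the photogrammetric survey conditions the pipeline is built for: an
almond-type orchard on a 6 x 7 m planting grid, flat or uniformly sloped
ground (up to ~10-15% rise/run), open-vase crowns modelled as upper
half-ellipsoids on a short trunk gap, three square reference panels
(white/grey/black, nominal visible reflectances 0.97/0.43/0.05) lying on the
ground near the field centre, and bloom expressed as bright flower points on
the outer crown shell. Every scene comes with a :class:`SceneTruth` holding
tree positions, true heights, analytic crown volumes and exact flower counts,
so downstream estimates can be scored against known values.

Randomness is consumed from per-component generators derived from the scene
seed in a fixed documented order (ground, trees by id, panels, flowers by
date), so identical (config, seed) pairs produce bitwise-identical clouds and
crown geometry stays frozen across the dates of a time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from .cloud import (
    ColoredPointCloud,
    LABEL_CANOPY,
    LABEL_FLOWER,
    LABEL_GROUND,
    LABEL_PANEL,
    concatenate,
)

PANEL_IDS = ("white", "grey", "black")


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic orchard scene.

    Distances are metres, densities points per m^2 (ground/panel) or per m^3
    (canopy), colors on the [0, 255] channel scale. Per-variety mappings are
    keyed by variety name; trees are assigned to varieties cyclically by id.
    """

    n_rows: int = 4
    n_cols: int = 6
    row_spacing: float = 7.0
    tree_spacing: float = 6.0
    margin: float = 4.0
    slope: float = 0.0            # rise/run along +x
    ground_z0: float = 100.0
    varieties: tuple[str, ...] = ("A", "B", "C")
    tree_height_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"A": (2.8, 3.2), "B": (3.3, 3.7), "C": (3.8, 4.2)}
    )
    crown_semiaxes: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {v: (1.5, 1.5, 2.5) for v in ("A", "B", "C")}
    )
    crown_base_height: float = 0.8
    canopy_point_density: float = 1000.0
    ground_point_density: float = 20.0
    panel_point_density: float = 600.0
    canopy_color_model: tuple[tuple[float, float, float], float] = ((60.0, 90.0, 50.0), 12.0)
    flower_color_model: tuple[tuple[float, float, float], float] = ((210.0, 205.0, 200.0), 8.0)
    ground_color_model: tuple[tuple[float, float, float], float] = ((70.0, 62.0, 55.0), 10.0)
    flower_density: float = 20.0  # flowers per m^3 of crown (single-date scenes)
    flower_min_height: float = 1.1
    panel_size: float = 0.45
    panel_reflectances: tuple[float, float, float] = (0.97, 0.43, 0.05)
    coordinate_noise_sd: float = 0.02
    color_noise_sd: float = 2.0
    missing_tree_ids: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols <= 0:
            raise ValueError("scene must contain at least one tree")
        if self.row_spacing <= 0 or self.tree_spacing <= 0:
            raise ValueError("tree spacings must be positive")
        if self.canopy_point_density <= 0 or self.ground_point_density <= 0:
            raise ValueError("point densities must be positive")
        if not 0 <= self.slope <= 0.15:
            raise ValueError("slope must be a rise/run fraction in [0, 0.15]")
        for refl in self.panel_reflectances:
            if not 0 < refl <= 1:
                raise ValueError("panel reflectances must lie in (0, 1]")
        for v, (a, b, c) in self.crown_semiaxes.items():
            if min(a, b, c) <= 0:
                raise ValueError(f"crown semiaxes for variety {v!r} must be positive")

    @property
    def field_width(self) -> float:
        return 2 * self.margin + (self.n_cols - 1) * self.tree_spacing

    @property
    def field_depth(self) -> float:
        return 2 * self.margin + (self.n_rows - 1) * self.row_spacing

    def ground_elevation(self, x, y):
        """Terrain plane: constant-gradient slope along +x."""
        return self.ground_z0 + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class PanelTruth:
    panel_id: str
    footprint: object  # shapely polygon
    reflectance: float
    nominal_brightness: float


@dataclass
class SceneTruth:
    """Exact per-tree and per-panel ground truth for one generated scene."""

    trees: pd.DataFrame  # tree_id, variety, x, y, true_height, a, b, c,
    #                      true_volume, true_flower_count
    panels: list[PanelTruth]
    terrain: dict
    seed: int

    def flower_counts(self) -> pd.Series:
        return self.trees.set_index("tree_id")["true_flower_count"]


def _tree_layout(config: SceneConfig) -> pd.DataFrame:
    rows = []
    tree_id = 0
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            rows.append({
                "tree_id": tree_id,
                "variety": config.varieties[tree_id % len(config.varieties)],
                "x": config.margin + c * config.tree_spacing,
                "y": config.margin + r * config.row_spacing,
            })
            tree_id += 1
    return pd.DataFrame(rows)


def _truncnorm_colors(rng, mean_rgb, sd, extra_sd, n):
    sd_total = float(np.hypot(sd, extra_sd))
    cols = rng.normal(loc=np.asarray(mean_rgb, float), scale=sd_total, size=(n, 3))
    return np.clip(cols, 0.0, 255.0)


def _sample_upper_half_ball(rng, n: int) -> np.ndarray:
    """Uniform points in the unit upper half-ball (z >= 0)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    rad = rng.uniform(0.0, 1.0, n) ** (1.0 / 3.0)
    pts = v * rad[:, None]
    pts[:, 2] = np.abs(pts[:, 2])
    return pts


def _sample_shell(rng, n: int, inner: float = 0.9) -> np.ndarray:
    """Uniform points in the outer shell of the unit upper half-ball."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.uniform(0.0, 1.0, n)
    rad = (inner ** 3 + u * (1.0 - inner ** 3)) ** (1.0 / 3.0)
    pts = v * rad[:, None]
    pts[:, 2] = np.abs(pts[:, 2])
    return pts


def _panel_footprints(config: SceneConfig) -> list[PanelTruth]:
    cx = config.field_width / 2.0
    gap_row = max(config.n_rows // 2, 1)
    cy = config.margin + (gap_row - 0.5) * config.row_spacing
    half = config.panel_size / 2.0
    panels = []
    spacing = config.panel_size + 0.35
    for i, (pid, refl) in enumerate(zip(PANEL_IDS, config.panel_reflectances)):
        px = cx + (i - 1) * spacing
        panels.append(PanelTruth(
            panel_id=pid,
            footprint=box(px - half, cy - half, px + half, cy + half),
            reflectance=refl,
            nominal_brightness=255.0 * refl,
        ))
    return panels


def generate_scene(config: SceneConfig,
                   flower_counts: Mapping[int, int] | None = None,
                   date_index: int = 0) -> tuple[ColoredPointCloud, SceneTruth]:
    """Generate one scene and its exact ground truth.

    ``flower_counts`` overrides the per-tree flower count (used by
    :func:`generate_time_series`); by default each tree carries
    ``round(flower_density * true_volume)`` flowers on its crown shell.
    """
    layout = _tree_layout(config)
    if layout.empty:
        raise ValueError("degenerate scene: no trees on the grid")

    rng_ground = np.random.default_rng([int(config.seed), 0])
    rng_trees = np.random.default_rng([int(config.seed), 1])
    rng_panels = np.random.default_rng([int(config.seed), 2])
    rng_flowers = np.random.default_rng([int(config.seed), 3, int(date_index)])

    parts: list[ColoredPointCloud] = []

    # --- ground (first in the stream order) ---
    area = config.field_width * config.field_depth
    n_ground = int(round(area * config.ground_point_density))
    gx = rng_ground.uniform(0.0, config.field_width, n_ground)
    gy = rng_ground.uniform(0.0, config.field_depth, n_ground)
    gz = config.ground_elevation(gx, gy)
    noise = config.coordinate_noise_sd
    if noise > 0:
        gx = gx + rng_ground.normal(0, noise, n_ground)
        gy = gy + rng_ground.normal(0, noise, n_ground)
        gz = gz + rng_ground.normal(0, noise, n_ground)
    gcol = _truncnorm_colors(rng_ground, config.ground_color_model[0],
                             config.ground_color_model[1],
                             config.color_noise_sd, n_ground)
    parts.append(ColoredPointCloud(
        gx, gy, gz, gcol[:, 0], gcol[:, 1], gcol[:, 2],
        class_label=np.full(n_ground, LABEL_GROUND, dtype=np.uint8),
    ))

    # --- trees, consumed strictly in id order ---
    truth_rows = []
    for row in layout.itertuples(index=False):
        a, b, c_nominal = config.crown_semiaxes[row.variety]
        h_lo, h_hi = config.tree_height_range[row.variety]
        true_height = rng_trees.uniform(h_lo, h_hi)
        c = true_height - config.crown_base_height
        if c <= 0:
            raise ValueError(
                f"tree {row.tree_id}: height {true_height:.2f} m does not "
                f"clear the crown base {config.crown_base_height} m"
            )
        volume = (2.0 / 3.0) * np.pi * a * b * c
        n_canopy = int(round(volume * config.canopy_point_density))
        base_z = config.ground_elevation(row.x, row.y) + config.crown_base_height
        unit = _sample_upper_half_ball(rng_trees, n_canopy)
        cx = row.x + a * unit[:, 0]
        cy = row.y + b * unit[:, 1]
        cz = base_z + c * unit[:, 2]
        if noise > 0:
            cx = cx + rng_trees.normal(0, noise, n_canopy)
            cy = cy + rng_trees.normal(0, noise, n_canopy)
            cz = cz + rng_trees.normal(0, noise, n_canopy)
        ccol = _truncnorm_colors(rng_trees, config.canopy_color_model[0],
                                 config.canopy_color_model[1],
                                 config.color_noise_sd, n_canopy)
        if flower_counts is not None:
            n_flowers = int(flower_counts.get(row.tree_id, 0))
        else:
            n_flowers = int(round(config.flower_density * volume))
        truth_rows.append({
            "tree_id": row.tree_id, "variety": row.variety,
            "x": row.x, "y": row.y, "true_height": true_height,
            "a": a, "b": b, "c": c, "true_volume": volume,
            "true_flower_count": n_flowers,
        })
        if row.tree_id in config.missing_tree_ids:
            continue
        if n_canopy > 0:
            parts.append(ColoredPointCloud(
                cx, cy, cz, ccol[:, 0], ccol[:, 1], ccol[:, 2],
                class_label=np.full(n_canopy, LABEL_CANOPY, dtype=np.uint8),
            ))

    # --- panels ---
    panels = _panel_footprints(config)
    for panel in panels:
        n_pan = max(int(round(config.panel_size ** 2 * config.panel_point_density)), 10)
        x0, y0, x1, y1 = panel.footprint.bounds
        px = rng_panels.uniform(x0, x1, n_pan)
        py = rng_panels.uniform(y0, y1, n_pan)
        pz = config.ground_elevation(px, py) + 0.01
        if noise > 0:
            pz = pz + rng_panels.normal(0, min(noise, 0.01), n_pan)
        value = 255.0 * panel.reflectance
        pcol = _truncnorm_colors(rng_panels, (value, value, value), 0.0,
                                 config.color_noise_sd, n_pan)
        parts.append(ColoredPointCloud(
            px, py, pz, pcol[:, 0], pcol[:, 1], pcol[:, 2],
            class_label=np.full(n_pan, LABEL_PANEL, dtype=np.uint8),
        ))

    # --- flowers, last; stream keyed by date so geometry stays fixed ---
    trees = pd.DataFrame(truth_rows)
    for row in trees.itertuples(index=False):
        if row.tree_id in config.missing_tree_ids or row.true_flower_count == 0:
            continue
        n_f = int(row.true_flower_count)
        base_z = config.ground_elevation(row.x, row.y) + config.crown_base_height
        fx = np.empty(0); fy = np.empty(0); fz = np.empty(0)
        # rejection-sample shell points until all satisfy the height floor
        while fx.size < n_f:
            m = max(2 * (n_f - fx.size), 32)
            unit = _sample_shell(rng_flowers, m)
            sx = row.x + row.a * unit[:, 0]
            sy = row.y + row.b * unit[:, 1]
            sz = base_z + row.c * unit[:, 2]
            if noise > 0:
                sx = sx + rng_flowers.normal(0, noise, m)
                sy = sy + rng_flowers.normal(0, noise, m)
                sz = sz + rng_flowers.normal(0, noise, m)
            keep = (sz - config.ground_elevation(sx, sy)) >= config.flower_min_height
            fx = np.concatenate([fx, sx[keep]])
            fy = np.concatenate([fy, sy[keep]])
            fz = np.concatenate([fz, sz[keep]])
        fx, fy, fz = fx[:n_f], fy[:n_f], fz[:n_f]
        fcol = _truncnorm_colors(rng_flowers, config.flower_color_model[0],
                                 config.flower_color_model[1],
                                 config.color_noise_sd, n_f)
        parts.append(ColoredPointCloud(
            fx, fy, fz, fcol[:, 0], fcol[:, 1], fcol[:, 2],
            class_label=np.full(n_f, LABEL_FLOWER, dtype=np.uint8),
        ))

    trees = trees[~trees["tree_id"].isin(config.missing_tree_ids)].reset_index(drop=True)
    truth = SceneTruth(
        trees=trees,
        panels=panels,
        terrain={"z0": config.ground_z0, "slope_x": config.slope, "slope_y": 0.0},
        seed=int(config.seed),
    )
    return concatenate(parts), truth


def match_crowns_to_truth(centroids: pd.DataFrame, truth: SceneTruth,
                          max_distance: float = 1.5) -> dict[int, int]:
    """Greedy nearest-centroid map from delineated crown ids to true trees.

    ``centroids`` needs tree_id/x/y columns (e.g. a metrics table). Pairs
    beyond ``max_distance`` stay unmatched. Used to score delineation and
    per-tree estimates against generator truth.
    """
    pairs = []
    for crown in centroids.itertuples(index=False):
        for tree in truth.trees.itertuples(index=False):
            d = float(np.hypot(crown.x - tree.x, crown.y - tree.y))
            if d <= max_distance:
                pairs.append((d, int(crown.tree_id), int(tree.tree_id)))
    pairs.sort()
    mapping: dict[int, int] = {}
    used: set[int] = set()
    for d, cid, tid in pairs:
        if cid in mapping or tid in used:
            continue
        mapping[cid] = tid
        used.add(tid)
    return mapping


BloomProfile = Callable[[str, int], float] | Mapping[str, Sequence[float]]


def _profile_value(profile: BloomProfile, variety: str, date_index: int) -> float:
    if callable(profile):
        value = float(profile(variety, date_index))
    else:
        value = float(profile[variety][date_index])
    if value < 0:
        raise ValueError("bloom profile must be non-negative everywhere")
    return value


def generate_time_series(config: SceneConfig, dates: Sequence,
                         bloom_profile: BloomProfile,
                         ) -> list[tuple[object, ColoredPointCloud, SceneTruth]]:
    """Generate one scene per date with bloom following a per-variety profile.

    Crown geometry, ground and panels are identical on every date (a single
    early-season survey window); only the flower points change. The true
    flower count of a tree on date ``d`` is
    ``round(profile(variety, d) * true_volume)``.
    """
    if len(dates) < 1:
        raise ValueError("need at least one date")
    if any(not (dates[i] < dates[i + 1]) for i in range(len(dates) - 1)):
        raise ValueError("dates must be strictly increasing")
    # volumes are fixed by (config, seed); generate once to read them
    _, base_truth = generate_scene(config, flower_counts={})
    out = []
    for d_idx, date in enumerate(dates):
        counts = {
            int(t.tree_id): int(round(
                _profile_value(bloom_profile, t.variety, d_idx) * t.true_volume))
            for t in base_truth.trees.itertuples(index=False)
        }
        cloud, truth = generate_scene(config, flower_counts=counts,
                                      date_index=d_idx)
        out.append((date, cloud, truth))
    return out
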