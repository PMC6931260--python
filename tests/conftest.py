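import numpy as np
import pytest

from orchardpheno.cloud import ColoredPointCloud
from orchardpheno.pipeline import process_date
from orchardpheno.synthetic import SceneConfig, generate_scene


def noise_free_config(**overrides) -> SceneConfig:
    """Default orchard with all stochastic jitter switched off: exact
    colors per class and exact geometry, so classification is decidable."""
    kw = dict(
        canopy_color_model=((60.0, 90.0, 50.0), 0.0),
        flower_color_model=((210.0, 205.0, 200.0), 0.0),
        ground_color_model=((70.0, 62.0, 55.0), 0.0),
        coordinate_noise_sd=0.0,
        color_noise_sd=0.0,
        seed=11,
    )
    kw.update(overrides)
    return SceneConfig(**kw)


def random_cloud(rng, n=100, **kw) -> ColoredPointCloud:
    return ColoredPointCloud(
        x=rng.uniform(0, 50, n), y=rng.uniform(0, 50, n),
        z=rng.uniform(90, 110, n),
        r=rng.integers(0, 256, n).astype(float),
        g=rng.integers(0, 256, n).astype(float),
        b=rng.integers(0, 256, n).astype(float), **kw)


@pytest.fixture(scope="session")
def default_scene():
    """One default 24-tree scene with realistic noise."""
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture(scope="session")
def processed_default(default_scene):
    cloud, truth = default_scene
    footprints = {p.panel_id: p.footprint for p in truth.panels}
    reflectances = {p.panel_id: p.reflectance for p in truth.panels}
    return process_date(cloud, footprints, date="d0",
                        panel_reflectances=reflectances), truth
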