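import numpy as np
import pytest

from plantreg.core import PointCloud
from plantreg.synth import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_cloud(rng, n=100, with_labels=False, scale=10.0):
    pts = rng.uniform(-scale, scale, (n, 3))
    colors = rng.integers(0, 256, (n, 3))
    labels = rng.integers(-1, 5, n) if with_labels else None
    return PointCloud(pts, colors, labels)


@pytest.fixture(scope="session")
def clean_scene():
    """Small noiseless 6-view scene shared across tests."""
    config = SceneConfig(rng_seed=5, points_per_cm2=10.0)
    views, truth = generate_scene(config)
    return config, views, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """Small noisy scene with outliers and dark edge points."""
    config = SceneConfig(
        rng_seed=9,
        points_per_cm2=12.0,
        noise_sigma=0.05,
        outlier_fraction=0.03,
        dark_edge_fraction=0.1,
    )
    views, truth = generate_scene(config)
    return config, views, truth
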