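import numpy as np
import pytest

import cabbagemorph as cm


@pytest.fixture(scope="session")
def camera():
    return cm.CameraModel(
        focal_length=1000.0,
        principal_point=(256.0, 256.0),
        camera_height=900.0,
        image_size=(512, 512),
    )


@pytest.fixture(scope="session")
def funnel_scene():
    """One noiseless funnel plant: 12 planar leaves, lengths 150-350 mm."""
    spec = cm.PlantSpec(n_leaves=12, leaf_lengths=(150.0, 350.0))
    return cm.build_scene([spec], seed=11)


@pytest.fixture(scope="session")
def funnel_render(funnel_scene):
    depth, labels = cm.render(funnel_scene, noise_sd=0.0, outlier_fraction=0.0, seed=11)
    return depth, labels


@pytest.fixture(scope="session")
def head_scene():
    """Funnel plant with a 90 mm spherical head tangent to the attachment point."""
    spec = cm.PlantSpec(n_leaves=12, leaf_lengths=(150.0, 350.0), head_radius=90.0)
    return cm.build_scene([spec], seed=5)


def rng_cloud(n, seed, scale=100.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(-scale, scale, size=(n, 3))
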