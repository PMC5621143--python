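import numpy as np
import pytest

from ocweed.features import SplitSpec, assemble_features
from ocweed.pipeline import prepare_calibration
from ocweed.scene_sim import TARGET, SceneConfig, simulate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic scene with its truth mask (seed 7)."""
    config = SceneConfig(seed=7)
    scene, mask = simulate_scene(config)
    return scene, mask, config


@pytest.fixture(scope="session")
def calibration(default_scene):
    """Balanced 2 x 1434 sample, 70/30 split, standardized on train targets."""
    scene, mask, _ = default_scene
    features = assemble_features(scene, mask)
    cal = prepare_calibration(features, per_class=1434, seed=7,
                              split_spec=SplitSpec(seed=7))
    cal["features"] = features
    return cal


@pytest.fixture(scope="session")
def train_targets(calibration):
    return calibration["train"].class_rows(TARGET)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250926)
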