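import numpy as np
import pytest

from nucleoprofile.simulate import (
    SceneConfig,
    render_ground_truth_round,
    render_scene,
    two_class_profiles,
)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 2-class field with exact truth (module-shared)."""
    cfg = SceneConfig(
        field_size=(320, 320),
        classes=two_class_profiles(2.0),
        target_count=12,
        overlap_policy="none",
        seed=11,
    )
    img, truth = render_scene(cfg)
    return cfg, img, truth


@pytest.fixture(scope="session")
def gt_round(small_scene):
    cfg, img, truth = small_scene
    gt = render_ground_truth_round(truth, cfg, shift=(5, -3))
    return gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
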