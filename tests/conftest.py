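import numpy as np
import pytest

from histopatch.synthetic import SceneSpec, make_scene, render_rgb


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_scene():
    """Noiseless 128×128 scene with 6 well-separated nuclei."""
    spec = SceneSpec(
        height=128,
        width=128,
        n_nuclei=6,
        radius_range=(6, 12),
        overlap_fraction=0.0,
        noise_sd=0.0,
        seed=1,
    )
    return make_scene(spec)


@pytest.fixture
def small_image(small_scene):
    return render_rgb(small_scene)


def scene_image(seed, **kwargs):
    """Render a scene with overrides; shared helper for parametrized tests."""
    defaults = dict(
        height=128,
        width=128,
        n_nuclei=6,
        radius_range=(6, 12),
        overlap_fraction=0.0,
        noise_sd=0.0,
    )
    defaults.update(kwargs)
    gt = make_scene(SceneSpec(seed=seed, **defaults))
    return gt, render_rgb(gt)
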