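import numpy as np
import pytest

from mdpcnet import nn
from mdpcnet.config import ModelConfig
from mdpcnet.scene import HsiScene
from mdpcnet.synth import SceneRecipe, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def float64_nn():
    """Run the numpy NN core in float64 for finite-difference comparisons."""
    old = nn.DTYPE
    nn.set_dtype(np.float64)
    yield
    nn.set_dtype(old)


@pytest.fixture
def tiny_model_config():
    """Smallest config that exercises every module path."""
    return ModelConfig(n_bands=8, n_classes=3, patch_size=5, stage_width=2,
                       pyramid_width=6, model_dim=8, n_heads=2, mlp_hidden=4,
                       n_tokens=2, dropout=0.0)


@pytest.fixture
def small_scene():
    """A quick 24x24 scene with 3 classes for sampling/I-O tests."""
    recipe = SceneRecipe(rows=24, cols=24, n_bands=12, n_classes=3,
                         n_parcels=9, seed=7, noise_sd=0.01)
    return render_scene(recipe)


def random_scene(rng: np.random.Generator, rows=8, cols=6, bands=12,
                 n_classes=3) -> HsiScene:
    cube = rng.random((rows, cols, bands))
    labels = rng.integers(0, n_classes + 1, size=(rows, cols))
    return HsiScene(cube=cube, labels=labels,
                    class_names=[f"c{i}" for i in range(1, n_classes + 1)])
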