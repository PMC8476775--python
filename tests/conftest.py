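import numpy as np
import pytest

from deephistoclass.config import CELL_TYPES, desk_config
from deephistoclass.model import HBNet
from deephistoclass.synthetic import SyntheticImageSpec, generate_images


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_dataset():
    """60 synthetic 64-px images split 40/10/10, with geometry masks."""
    spec = SyntheticImageSpec(n_images=60, seed=7)
    images, masks = generate_images(spec, return_masks=True)
    for i, im in enumerate(images):
        im.split = "train" if i < 40 else "validation" if i < 50 else "test"
    return images, masks, spec


@pytest.fixture(scope="session")
def tiny_fit(small_dataset):
    """A cheaply trained model reused by model/uncertainty/integration tests."""
    images, _, _ = small_dataset
    cfg = desk_config(epochs=4, fc_layer_sizes=(64, 64), cnn_feature_dim=32,
                      seed=3)
    model = HBNet(images, config=cfg)
    return model, model.fit(seed=3)


@pytest.fixture
def label_matrix(rng):
    return rng.integers(0, 2, size=(30, len(CELL_TYPES)))
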