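import numpy as np
import pytest

from layerprobe.features import TinyNetExtractor
from layerprobe.synthetic import make_transformation_grid


@pytest.fixture(scope="session")
def extractor():
    return TinyNetExtractor(seed=0)


@pytest.fixture(scope="session")
def grid_set():
    """Default transformation grid: 2 objects x 6 sizes x 9 rotations."""
    return make_transformation_grid(seed=1)


@pytest.fixture(scope="session")
def grid_features(extractor, grid_set):
    """Train-fitted per-layer feature matrices for the default grid."""
    from layerprobe.pipeline import _layer_feature_matrices

    items = list(grid_set)
    train_mask = np.array([it.role == "train" for it in items])
    mats = _layer_feature_matrices(extractor, items, train_mask, include_pixels=True)
    return mats, items, train_mask
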