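import warnings

import numpy as np
import pytest

from neurofb.decoder import AUTOMATIC_ORIENTATIONS, train_classifier
from neurofb.v1_model import VoxelModel

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def mini_model():
    """50-voxel line of voxels with independent noise; fast stand-in brain."""
    return VoxelModel(
        grid_shape=(50, 1, 1),
        fraction_tuned=0.4,
        noise_sigma=0.5,
        noise_kind="iid",
        assignment_seed=0,
    )


@pytest.fixture(scope="session")
def mini_classifier(mini_model):
    patterns, labels = mini_model.generate_training_examples(
        AUTOMATIC_ORIENTATIONS, n_per_class=30, snr=2.0, rng_seed=7
    )
    return train_classifier(patterns, labels, AUTOMATIC_ORIENTATIONS, rng_seed=1)


@pytest.fixture(scope="session")
def grf_model():
    """Small 6x6x6 cube with spatially correlated spontaneous activity."""
    return VoxelModel(grid_shape=(6, 6, 6), noise_sigma=0.5, noise_kind="grf")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
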