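import numpy as np
import pytest

from branchmorph import model as bmodel
from branchmorph import synthetic as syn


def make_training_scenes(n: int, size: int = 128, seed0: int = 0):
    """Small scenes with a trunk and a few branches, sized for CPU runs."""
    pairs = []
    for s in range(seed0, seed0 + n):
        spec = syn.random_scene(
            seed=s, height=size, width=size,
            n_branches=(2, 4), branch_length=(30, 80), branch_width=(2, 6),
        )
        image, mask, _ = syn.render_scene(spec)
        pairs.append((image, mask))
    return pairs


SMALL_UNET = bmodel.UNetConfig(base_channels=8, se_reduction=4)
OVERFIT_TC = bmodel.TrainConfig(lr0=3e-3, batch_size=1, epochs=50, freeze_epochs=0, seed=0)


@pytest.fixture(scope="session")
def overfit_pairs():
    return make_training_scenes(4)


@pytest.fixture(scope="session")
def overfit_net(overfit_pairs):
    """A small network overfitted on four synthetic scenes (50 epochs)."""
    net = bmodel.build_model(SMALL_UNET, seed=0)
    history = bmodel.train(net, overfit_pairs, OVERFIT_TC)
    return net, history


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
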