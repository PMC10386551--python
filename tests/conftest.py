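import numpy as np
import pytest

import fxpreg as fr
from fxpreg.model import NetworkWeights, TrainConfig
from fxpreg.phantom import concat_pair

# Desk-scale study conditions: 2500 phantom pairs split 2000/250/250, the
# compact training protocol (500 epochs at lr 1e-3, preserving the full-scale
# optimization budget lr x steps; see docs/methods.md).
DESK_N_IMAGES = 2500
DESK_DATA_SEED = 11
DESK_TRAIN = TrainConfig(learning_rate=1e-3, batch_size=50, epochs=500, seed=7)


def stack_inputs(pairs):
    """Concatenated network inputs and normalized targets for a pair list."""
    x = np.stack([concat_pair(p.fixed, p.moving) for p in pairs])
    t = np.stack([p.gt_norm for p in pairs])
    return x, t


@pytest.fixture(scope="session")
def desk_experiment():
    """The trained desk-scale experiment shared by the slow tests."""
    ds = fr.build_dataset(
        n_images=DESK_N_IMAGES, seed=DESK_DATA_SEED, split=(0.8, 0.1, 0.1)
    )
    w, hist = fr.train(ds, DESK_TRAIN)
    calib, _ = stack_inputs(ds.train[:200])
    return {"ds": ds, "w": w, "hist": hist, "calib": calib}


@pytest.fixture(scope="session")
def tiny_dataset():
    return fr.build_dataset(n_images=30, seed=5, split=(0.6, 0.2, 0.2))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def grid_exact_setup(seed: int = 3):
    """Weights and an input whose entire forward pass is representable.

    Everything lives on the 2**-2 grid with small magnitudes, so with a
    Q16.12 word every intermediate product and sum is exactly representable
    and the quantized pipeline must reproduce the float pipeline bit for
    float bit.  Head weights are sparse to keep head sums in range.
    """
    rng = np.random.default_rng(seed)

    def grid(shape, lo, hi):
        return rng.integers(lo * 4, hi * 4 + 1, size=shape) / 4.0

    heads = {}
    for name in ("head_rot_w", "head_dx_w", "head_dy_w"):
        h = np.zeros(784)
        idx = rng.choice(784, size=8, replace=False)
        h[idx] = rng.integers(-2, 3, size=8) / 4.0
        heads[name] = h
    w = NetworkWeights(
        conv1_w=grid((2, 2, 3, 8), -0.5, 0.5),
        conv1_b=grid((8,), -0.5, 0.5),
        conv2_w=grid((2, 2, 8, 16), -0.5, 0.5),
        conv2_b=grid((16,), -0.5, 0.5),
        **heads,
    )
    x = rng.integers(0, 5, size=(32, 32, 3)) / 4.0
    return w, x
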