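import numpy as np
import pytest

from abunet import ModelConfig, SyntheticSpec, build_unet, generate_dataset


@pytest.fixture(scope="session")
def small_net():
    """Depth-2 maxpool-dropout network shared by read-only tests."""
    return build_unet(
        ModelConfig(depth=2, base_filters=4, n_classes=3, variant="maxpool_dropout"),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_image():
    return np.random.default_rng(11).random((16, 16)).astype(np.float32)


@pytest.fixture(scope="session")
def tiny_dataset():
    """20 small 5-class images for training-flavoured tests."""
    spec = SyntheticSpec(n_images=20, height=32, width=32, n_classes=5, seed=3)
    return generate_dataset(spec)


def random_probmap(rng, h, w, c):
    p = rng.random((h, w, c))
    return p / p.sum(axis=-1, keepdims=True)


def random_stack(rng, t, h, w, c):
    p = rng.random((t, h, w, c))
    return p / p.sum(axis=-1, keepdims=True)
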