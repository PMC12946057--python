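import numpy as np
import pytest

from taha import ModelConfig, VisionTransformer


@pytest.fixture
def tiny_config():
    return ModelConfig(image_size=16, patch_size=8, channels=3, depth=2,
                       heads_per_layer=[2, 2], embed_dim=8, mlp_dim=16,
                       n_classes=2, use_cls_token=True)


@pytest.fixture
def tiny_model(tiny_config):
    return VisionTransformer(tiny_config, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_batch(rng, tiny_config):
    s = tiny_config.image_size
    return rng.random((3, s, s, tiny_config.channels))
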