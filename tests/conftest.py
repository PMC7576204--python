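"""Shared fixtures: small synthetic datasets and models."""

import numpy as np
import pytest

from deephl.features import build_feature_tensor
from deephl.model import DeepHLNet, ModelConfig
from deephl.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    cfg = SyntheticConfig(n_per_class=6, traj_len=40, seed=7)
    trajs, truths = generate_dataset(cfg)
    return cfg, trajs, truths


@pytest.fixture(scope="session")
def tiny_bundle(tiny_dataset):
    _, trajs, _ = tiny_dataset
    return build_feature_tensor(trajs)


@pytest.fixture(scope="session")
def tiny_model(tiny_bundle):
    cfg = ModelConfig(l_max=tiny_bundle.l_max, n_features=2,
                      layers_per_stack=1, units=4)
    return DeepHLNet(cfg, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
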