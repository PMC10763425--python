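import dataclasses

import numpy as np
import pytest

from pneumonet.model_zoo import NetworkConfig
from pneumonet.synthetic_xray import (
    DESK_SPEC,
    LesionParams,
    PhantomSpec,
    generate_dataset,
    split_dataset,
)
from pneumonet.train_eval import TrainConfig


#: tiny configuration used by the fast training-loop tests
TINY_NET = NetworkConfig(input_size=(32, 32, 1), stem_channels=4, n_blocks=1,
                         branch_reduction=2)
TINY_SPEC = PhantomSpec(image_size=32, n_pneumonia=40, n_normal=20,
                        noise_sd=0.0, seed=7)
TINY_TRAIN = TrainConfig(lr0=3e-3, max_epochs=2, batch_size=16, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset():
    samples, manifest = generate_dataset(TINY_SPEC)
    return samples, manifest


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    samples, _ = tiny_dataset
    return split_dataset(samples, (28, 14), (12, 6), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
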