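import logging

import numpy as np
import pytest

from fundusfair.synthetic import SyntheticSpec, generate_dataset

logging.getLogger("fundusfair").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small-image default-bias spec used across pipeline tests."""
    return SyntheticSpec.default(seed=7, image_size=(32, 40))


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate_dataset(tiny_spec, 240)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
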