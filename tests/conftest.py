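import numpy as np
import pytest

from veincode import SynthConfig, generate_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small, fast dataset: 6 fingers x 8 samples of 48x96 px."""
    return SynthConfig(n_subjects=6, samples_per_subject=8, height=48, width=96,
                       n_veins=4, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    return generate_arrays(tiny_cfg)
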