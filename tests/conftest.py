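import numpy as np
import pytest

from threatdyn.synthetic import SynthConfig, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small complete synthetic study shared across tests (8 participants)."""
    return gen_dataset(SynthConfig(n_participants=8, seed=42, n_unusable=0))


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("tinydata")
    gen_dataset(SynthConfig(n_participants=8, seed=42, n_unusable=0), out_dir=out)
    return out
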