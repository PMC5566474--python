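import numpy as np
import pytest

from cfseq.core import Fragment, GenomeSequence
from cfseq.simulate import SimConfig, make_genome


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def genome(default_config) -> GenomeSequence:
    g, _runs = make_genome(default_config)
    return g


@pytest.fixture(scope="session")
def run_census(default_config):
    _g, runs = make_genome(default_config)
    return runs


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
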