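import numpy as np
import pytest

from rnaembed.model import ModelConfig, init_params
from rnaembed.seqio import RnaSequence


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    return ModelConfig(D=24, n_layers=2, H=4, ffn_dim=96, max_len=200)


@pytest.fixture
def tiny_params(tiny_config):
    return init_params(tiny_config, np.random.default_rng(7))


@pytest.fixture
def seq10():
    return RnaSequence("s10", "ACGUACGUAC")


def random_sequence(rng, n, sid="r"):
    return RnaSequence(sid, "".join(rng.choice(list("ACGU"), size=n)))
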