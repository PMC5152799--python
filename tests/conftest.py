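import numpy as np
import pytest

from burstkin import GeneConstruct, build_loop_function


@pytest.fixture
def construct_3p() -> GeneConstruct:
    """24-loop MS2 cassette at the 3' end of a 1800-bp leader (the hb reporter)."""
    return GeneConstruct(pre_cassette_steps=12, cassette_steps=12, post_cassette_steps=0)


@pytest.fixture
def construct_5p() -> GeneConstruct:
    """Cassette at the 5' end followed by a 3000-bp non-binding tail."""
    return GeneConstruct(pre_cassette_steps=0, cassette_steps=12, post_cassette_steps=20)


@pytest.fixture
def loop_3p(construct_3p):
    return build_loop_function(construct_3p)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160)
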