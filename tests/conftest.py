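import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def rank1_goal(rng):
    from bowtie_evo import generate_goal

    return generate_goal(6, 1, 60.0, rng)
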