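import numpy as np
import pytest
from hypothesis import settings

from boolpop.examples import example_network, ladder_network

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def example3():
    """The 3-node worked-example network (A ← !B, B ← A&C, C ← A|B)."""
    return example_network()


@pytest.fixture(scope="session")
def ladder6():
    """6-node feedforward ladder toy with a delayed inhibitor."""
    return ladder_network()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
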