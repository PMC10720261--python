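import numpy as np
import pytest

from hpslab.params import load_parameter_table
from hpslab.synthetic import ToySequenceSpec, make_toy_system
from hpslab.topology import build_topology


@pytest.fixture(scope="session")
def table():
    return load_parameter_table()


@pytest.fixture(scope="session")
def toy_table():
    """Parameter table extended with the neutral toy bead ``X``."""
    _, t = make_toy_system(ToySequenceSpec("sticky_homopolymer", length=2, stickiness=0.7))
    return t


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def decamer(toy_table):
    """A single flexible 10-bead homopolymer chain."""
    return build_topology("X" * 10, toy_table)
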