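import numpy as np
import pytest

from gagesd import synth
from gagesd.prep import prepare_charged


@pytest.fixture(scope="session")
def helix_template():
    """Default 60-residue charged helix template + sequence."""
    return synth.make_template()


@pytest.fixture(scope="session")
def small_template():
    """Compact 30-residue template used for solver-heavy tests."""
    charged = {12: "K", 15: "R", 18: "K", 21: "K", 5: "D", 26: "E"}
    structure, seq = synth.make_template(30, charged, id="template")
    return structure, seq, [12, 15, 18, 21]


@pytest.fixture(scope="session")
def small_charged(small_template):
    structure, _seq, _site = small_template
    return prepare_charged(structure, ph=7.4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
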