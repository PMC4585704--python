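import pytest

from alphoid import load_builtin_consensuses
from alphoid.synthetic import SimParams, simulate_array


@pytest.fixture(scope="session")
def cset():
    return load_builtin_consensuses()


@pytest.fixture(scope="session")
def ggo(cset):
    return cset["GGO_consensus"]


@pytest.fixture(scope="session")
def sf2_clean(cset):
    """Zero-noise SF2 array, 4 HOR units, with truth."""
    return simulate_array(SimParams(sf="SF2", n_units=4, sub_rate=0.0, seed=1), cset)


@pytest.fixture(scope="session")
def sf1_clean(cset):
    """Zero-noise SF1 array, 6 HOR units, with truth."""
    return simulate_array(SimParams(sf="SF1", n_units=6, sub_rate=0.0, seed=1), cset)
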