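import numpy as np
import pytest

from hbsyntax import compile_iupac


@pytest.fixture
def pbx():
    return compile_iupac("TGATNNATKR", name="PBX-HOX")


@pytest.fixture
def meis():
    return compile_iupac("CTGTCA", name="MEIS-PREP")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])
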