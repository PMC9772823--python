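import numpy as np
import pytest

from tcrbseq import build_synthetic_locus
from tcrbseq.annotate import Aligner


@pytest.fixture(scope="session")
def locus():
    return build_synthetic_locus(seed=1)


@pytest.fixture(scope="session")
def aligner(locus):
    return Aligner(locus)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
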