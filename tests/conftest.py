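import numpy as np
import pytest

from satevo.align import ScoringScheme


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
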