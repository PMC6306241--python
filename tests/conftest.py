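import numpy as np
import pytest
from hypothesis import settings

from allelecrispr import demo_target

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def target():
    return demo_target()


@pytest.fixture(scope="session")
def target_jxb():
    return demo_target(name="demo_locus_jxb", cross="JxB")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
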