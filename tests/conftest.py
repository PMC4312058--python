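import numpy as np
import pytest

from ylineage.haplogroups import default_tree
from ylineage.types import STRHaplotype, yfiler_panel


@pytest.fixture(scope="session")
def panel():
    return yfiler_panel()


@pytest.fixture(scope="session")
def tree():
    return default_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(20150130)


def make_hap(loci, values):
    """Integer haplotype on generic loci."""
    return STRHaplotype(dict(zip(loci, values)))


@pytest.fixture
def hap_factory():
    return make_hap
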