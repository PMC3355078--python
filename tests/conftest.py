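import numpy as np
import pytest

from karyocin.chromosomes import default_table
from karyocin.karyotype import Karyotype


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def haploid():
    return Karyotype.uniform(1)


@pytest.fixture()
def diploid():
    return Karyotype.uniform(2)
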