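import numpy as np
import pytest

from ecesim import CodeTable, make_fixture, random_genome


@pytest.fixture(scope="session")
def table() -> CodeTable:
    return CodeTable.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_genome():
    return make_fixture("toy_genome", 0)


@pytest.fixture(scope="session")
def random_genomes(table):
    """A bank of developed-scale random genomes shared across tests."""
    rng = np.random.default_rng(2024)
    return [random_genome(1800, rng) for _ in range(100)]
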