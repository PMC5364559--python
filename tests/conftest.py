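import numpy as np
import pytest

from protclass import AMINO_ACIDS, ProteinRecord, load_aaindex


def make_random_record(rng, length, rid="r"):
    letters = rng.choice(list(AMINO_ACIDS), size=length)
    return ProteinRecord(id=rid, sequence="".join(letters))


@pytest.fixture(scope="session")
def aaindex_table():
    return load_aaindex()


@pytest.fixture(scope="session")
def toy_table(aaindex_table):
    """Five complete indices from the packaged snapshot."""
    return aaindex_table.subset(list(aaindex_table.ids[:5]))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_records(rng):
    lengths = rng.integers(2, 201, size=30)
    return [make_random_record(rng, int(n), rid=f"s{i}") for i, n in enumerate(lengths)]
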