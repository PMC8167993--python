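import numpy as np
import pytest

from mkldbp import make_fixture_dataset
from mkldbp.seq_features import FeatureMatrix, load_property_table
from mkldbp.sequence_io import AMINO_ACIDS, ProteinRecord


@pytest.fixture(scope="session")
def property_table():
    return load_property_table()


@pytest.fixture(scope="session")
def small_dataset():
    """20 + 20 labelled records with profiles, strong class signal."""
    return make_fixture_dataset(20, 20, (60, 90), 0.8, seed=1)


@pytest.fixture(scope="session")
def null_dataset():
    """Balanced dataset with zero class signal."""
    return make_fixture_dataset(20, 20, (60, 90), 0.0, seed=3)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)])


def random_record(rng: np.random.Generator, length: int, rid: str = "r") -> ProteinRecord:
    return ProteinRecord(id=rid, sequence=random_sequence(rng, length))


def random_features(rng, n, d, name="F", ids=None) -> FeatureMatrix:
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    return FeatureMatrix(name, rng.uniform(size=(n, d)), ids)
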