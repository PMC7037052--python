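import numpy as np
import pytest

from bbbperm.io import (
    load_retention_params,
    load_test_compounds,
    load_training_set,
)
from bbbperm.models import AbrahamLFER


@pytest.fixture(scope="session")
def retention_table():
    return load_retention_params()


@pytest.fixture(scope="session")
def training_table():
    return load_training_set()


@pytest.fixture(scope="session")
def test_table():
    return load_test_compounds()


@pytest.fixture(scope="session")
def lfer(training_table):
    return AbrahamLFER().fit(
        training_table[["E", "S", "A", "B", "V"]],
        training_table["log_bb_exp"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20200123)
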