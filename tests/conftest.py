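import numpy as np
import pytest

from acpcnn import (
    DatasetEncoder,
    SyntheticSpec,
    generate_synthetic,
    load_property_table,
    load_substitution_matrix,
)


@pytest.fixture(scope="session")
def property_table():
    return load_property_table()


@pytest.fixture(scope="session")
def blosum62():
    return load_substitution_matrix()


@pytest.fixture(scope="session")
def encoder(property_table, blosum62):
    return DatasetEncoder(property_table, blosum62)


@pytest.fixture(scope="session")
def motif_dataset():
    """Strong-signal synthetic set: every positive carries the motif."""
    return generate_synthetic(
        SyntheticSpec(n_pos=60, n_neg=60, signal_prob=1.0, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
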