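import numpy as np
import pytest

from thetagamma import (
    build_network,
    make_nonorthogonal_set,
    make_orthogonal_set,
    success_table,
    train_sequences,
)


@pytest.fixture(scope="session")
def orth_set():
    return make_orthogonal_set()


@pytest.fixture(scope="session")
def nonorth_set():
    return make_nonorthogonal_set()


@pytest.fixture(scope="session")
def trained_orth(orth_set):
    return train_sequences(build_network(), orth_set, seed=0)


@pytest.fixture(scope="session")
def trained_nonorth(nonorth_set):
    return train_sequences(build_network(), nonorth_set, seed=0)


@pytest.fixture(scope="session")
def basal_table_orth(trained_orth, orth_set):
    return success_table(trained_orth, orth_set, n_runs=10, duration=1.0, seed=42)


@pytest.fixture(scope="session")
def basal_table_nonorth(trained_nonorth, nonorth_set):
    return success_table(trained_nonorth, nonorth_set, n_runs=10, duration=1.0, seed=42)
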