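"""Shared fixtures: one seeded synthetic dataset reused across test modules."""

import pytest

from protect.feature_matrix import build_feature_matrix
from protect.ppi_modules import detect_modules
from protect.synthetic_fixtures import SimulationConfig, simulate_dataset
from protect.training_set import make_training_table

CELL_TYPE = "CT00"


@pytest.fixture(scope="session")
def dataset():
    """Default-condition synthetic dataset (seed 1)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def modules(dataset):
    assignment, catalog = detect_modules(dataset.network)
    return assignment, catalog


@pytest.fixture(scope="session")
def training_table(dataset):
    return make_training_table(
        dataset.genome, dataset.contacts, dataset.genome.expression, CELL_TYPE, seed=1
    )


@pytest.fixture(scope="session")
def feature_data(dataset, modules, training_table):
    _, catalog = modules
    X, tf_matrix = build_feature_matrix(
        training_table, dataset.genome, dataset.network, catalog, CELL_TYPE
    )
    return X, tf_matrix
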