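import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from chiscreen.datasets import load_alanine_scan_table
from chiscreen.matrix import InteractionMatrix, reverse_weights
from chiscreen.structure import distance_table
from chiscreen.synthetic import (
    SyntheticConfig,
    generate_filament,
    generate_replicates,
    plant_alleles_and_matrix,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_matrix() -> InteractionMatrix:
    """4 alleles x 5 genes with a mix of scores and an all-zero column."""
    scores = pd.DataFrame(
        [
            [1, 0, 2, 3, 0],
            [0, 0, 0, 1, 0],
            [2, 2, 0, 0, 0],
            [0, 3, 1, 0, 0],
        ],
        index=["a1", "a2", "a3", "a4"],
        columns=["g1", "g2", "g3", "g4", "g5"],
    )
    return InteractionMatrix(scores=scores)


@pytest.fixture(scope="session")
def table1():
    """The packaged 32-allele annotation table and its interaction counts."""
    annotations, degrees = load_alanine_scan_table()
    return annotations, degrees


@pytest.fixture(scope="session")
def synthetic_default():
    """One default-condition synthetic dataset, shared across tests."""
    cfg = SyntheticConfig(seed=11)
    model, topo = generate_filament(cfg)
    matrix, annotations, truth = plant_alleles_and_matrix(cfg, model)
    return cfg, model, topo, matrix, annotations, truth


@pytest.fixture(scope="session")
def synthetic_distance_table(synthetic_default):
    cfg, model, topo, matrix, annotations, truth = synthetic_default
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = distance_table(annotations, reverse_weights(matrix), model, topo)
    return result.table


@pytest.fixture(scope="session")
def synthetic_replicates(synthetic_default):
    cfg, _, _, _, _, truth = synthetic_default
    return generate_replicates(truth, cfg)


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric zero-diagonal distance matrix (ties improbable)."""
    d = rng.uniform(0.1, 10.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d
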