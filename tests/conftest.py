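import numpy as np
import pytest

from phenocell.containers import GeneMatrix, PhenotypeVector
from phenocell.io import RunConfig


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal binary dataset shared across tests."""
    from phenocell.synthetic import generate

    return generate(n_genes=240, n_cells=120, n_samples=30, n_groups=3,
                    effect=3.0, marker_size=30, seed=7)


@pytest.fixture(scope="session")
def small_config():
    return RunConfig(min_cells_per_gene=5, n_pcs=6, knn_k=10, random_seed=7,
                     alpha_grid=(0.1, 0.5, 0.9), n_lambda=8, cv_folds=3)


@pytest.fixture
def toy_bulk():
    return GeneMatrix(
        ["g1", "g2", "g3", "g4"],
        ["s1", "s2", "s3"],
        np.array([[1.0, 2, 3], [0, 1, 7], [3, 3, 3], [2, 0, 1]]),
        stage="raw_counts",
    )


@pytest.fixture
def binary_pheno():
    return PhenotypeVector(["s1", "s2", "s3", "s4"], "binary",
                           y=np.array([1.0, 0, 1, 0]))


def rng(seed=0):
    return np.random.default_rng(seed)
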