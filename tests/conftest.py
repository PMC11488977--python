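import numpy as np
import pytest

from scanno import (
    MarkerCatalog,
    ExpressionMatrix,
    SimConfig,
    generate,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Small but structured synthetic dataset for fast unit tests."""
    return generate(SimConfig(
        n_cells=150, n_genes=60, n_types=3, markers_per_type=5,
        n_pathways=8, embed_dim=8, seed=7,
    ))


@pytest.fixture()
def toy_expression():
    rng = np.random.default_rng(0)
    counts = rng.poisson(2.0, size=(20, 10)).astype(float)
    return ExpressionMatrix(
        cell_ids=[f"c{i}" for i in range(20)],
        gene_ids=[f"G{i}" for i in range(10)],
        counts=counts,
    )


@pytest.fixture()
def toy_catalog():
    return MarkerCatalog(
        type_names=["A", "B", "C"],
        markers={"A": ["G0", "G1", "G2"], "B": ["G3", "G4"], "C": ["G5", "G2"]},
    )
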