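import numpy as np
import pytest

from editome import (
    BinaryEditingMatrix,
    GroupSpec,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_truth():
    """Small divergence-free dataset with planted edits, shared across tests."""
    config = SimulationConfig(
        n_genes=6,
        gene_length_range=(60, 120),
        groups={
            "high": GroupSpec(n_species=4, c2u_level=2.8, u2c_fraction=0.05),
            "low": GroupSpec(n_species=4, c2u_level=0.8, u2c_fraction=0.05),
        },
        seed=42,
    )
    return simulate_dataset(config)


@pytest.fixture
def random_binary_matrix():
    """Seeded 10 x 50 binary matrix with no all-zero column."""
    rng = np.random.default_rng(7)
    cells = rng.integers(0, 2, size=(10, 50)).astype(np.uint8)
    cells[0, cells.sum(axis=0) == 0] = 1
    return BinaryEditingMatrix(
        taxa=[f"sp{i:02d}" for i in range(10)],
        characters=[("g1", j + 1) for j in range(50)],
        cells=cells,
    )
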