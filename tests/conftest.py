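import numpy as np
import pandas as pd
import pytest

import gutlinks as gl


@pytest.fixture
def tiny_table():
    """Hand-sized count table: 4 samples x 6 OTUs."""
    df = pd.DataFrame(
        [[4, 0, 1, 5, 0, 10],
         [1, 2, 0, 5, 0, 12],
         [0, 5, 2, 5, 1, 7],
         [3, 3, 3, 3, 3, 5]],
        index=["s1", "s2", "s3", "s4"],
        columns=[f"o{j}" for j in range(1, 7)],
    )
    return gl.OtuTable(df)


@pytest.fixture(scope="session")
def planted_block_dataset():
    """n=200 samples, 50 OTUs, one 5-OTU block at basis correlation 0.8."""
    cfg = gl.SimulationConfig(n_samples_per_cell=25, n_otus=50, depth=20000,
                              n_blocks=1, block_size=5, block_correlation=0.8,
                              n_stage_otus=0, n_group_otus=0, seed=7)
    table, meta, tree, tax, truth = gl.simulate_dataset(cfg)
    return table, meta, tree, tax, truth


@pytest.fixture(scope="session")
def planted_block_sparcc(planted_block_dataset):
    table = planted_block_dataset[0]
    return gl.sparcc_correlations(table, seed=11)


@pytest.fixture(scope="session")
def two_blocks_dataset():
    """n=200 samples, 50 OTUs, two 8-OTU blocks at basis correlation 0.9."""
    cfg = gl.SimulationConfig(n_samples_per_cell=25, n_otus=50, depth=20000,
                              n_blocks=2, block_size=8, block_correlation=0.9,
                              n_stage_otus=0, n_group_otus=0, seed=1)
    table, meta, tree, tax, truth = gl.simulate_dataset(cfg)
    return table, meta, tree, tax, truth


@pytest.fixture(scope="session")
def two_blocks_sparcc(two_blocks_dataset):
    table = two_blocks_dataset[0]
    return gl.sparcc_correlations(table, seed=2)


def make_corr(matrix, ids=None):
    """CorrelationMatrix from a plain array (test helper)."""
    matrix = np.asarray(matrix, dtype=float)
    if ids is None:
        ids = [f"o{i}" for i in range(matrix.shape[0])]
    from gutlinks.sparcc import CorrelationMatrix
    return CorrelationMatrix(
        rho=pd.DataFrame(matrix, index=ids, columns=ids))
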