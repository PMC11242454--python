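import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from rhizobiome.containers import FeatureTable
from rhizobiome.simulate import AssemblyRegime, simulate_dataset


@pytest.fixture
def four_tip_tree() -> TreeNode:
    """((A:1,B:2):0.5,(C:1,D:1):0.5) — two clades, hand-checkable."""
    return TreeNode.read(io.StringIO("((A:1.0,B:2.0):0.5,(C:1.0,D:1.0):0.5);"))


@pytest.fixture
def small_table() -> FeatureTable:
    data = pd.DataFrame(
        [[5, 0, 3, 2], [0, 4, 1, 5], [2, 2, 2, 2]],
        index=["S1", "S2", "S3"],
        columns=["A", "B", "C", "D"],
    )
    return FeatureTable(data)


@pytest.fixture(scope="session")
def dataset():
    """Desk-scale simulated study reused by the slower integration tests."""
    return simulate_dataset(
        n_cultivars=8,
        n_replicates=3,
        n_taxa=120,
        depth=2000,
        regime=AssemblyRegime("homogeneous_selection", selection_sd=0.5),
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
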