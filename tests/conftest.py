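import io

import numpy as np
import pytest
from skbio import TreeNode

from ecoassembly.core import CommunityTable, TraitTable


def tree_from_newick(nwk: str) -> TreeNode:
    return TreeNode.read(io.StringIO(nwk), format="newick")


@pytest.fixture
def small_table():
    """3 samples x 4 taxa with distinct presence patterns."""
    return CommunityTable(
        ["S1", "S2", "S3"],
        ["A", "B", "C", "D"],
        np.array([[5, 3, 0, 0],
                  [0, 2, 6, 0],
                  [1, 1, 1, 1]]),
    )


@pytest.fixture
def four_tip_tree():
    return tree_from_newick("((A:1,B:2):0.5,(C:0.75,D:0.25):1.5);")


@pytest.fixture
def trait_table():
    return TraitTable(
        ["A", "B", "C", "D"],
        sulfate_production=np.array([10.0, 2.0, 5.0, 0.5]),
        nitrate_consumption=np.array([12.0, 3.0, 6.0, 0.4]),
        tetrathionate_producer=np.array([False, True, False, False]),
    )
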