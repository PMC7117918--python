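import io

import numpy as np
import pytest
from hypothesis import settings

from ncmkit import OtuTable
from ncmkit.core_io import validate_tree
from skbio import TreeNode

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")

THREE_TIP_NEWICK = "((A:1,B:1):0.5,C:1.5);"


def tree_from_string(newick: str) -> TreeNode:
    return validate_tree(TreeNode.read(io.StringIO(newick), format="newick"))


@pytest.fixture
def three_tip_tree():
    return tree_from_string(THREE_TIP_NEWICK)


@pytest.fixture
def small_table():
    return OtuTable(("OTU_1", "OTU_2", "OTU_3"), ("s1", "s2"),
                    np.array([[5, 0], [2, 8], [0, 1]]))
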