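import numpy as np
import pytest
from hypothesis import settings

from traitpath.coding import StateCoding
from traitpath.treeio import read_newick

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def four_tip_tree():
    return read_newick("(((A:0.3,B:0.7):0.4,C:1.1):0.2,D:0.9);")


@pytest.fixture
def four_tip_coding():
    return StateCoding({"A": "H", "B": "S", "C": "?", "D": "A"})


@pytest.fixture
def ten_tip_tree():
    # fixed mildly unbalanced tree with heterogeneous branch lengths
    return read_newick(
        "((((A:0.2,B:0.5):0.3,(C:0.4,D:0.1):0.6):0.2,"
        "((E:0.7,F:0.3):0.4,G:0.9):0.3):0.2,"
        "((H:0.5,I:0.2):0.6,J:1.1):0.4);"
    )


@pytest.fixture
def ten_tip_coding():
    return StateCoding(
        {
            "A": "H", "B": "H", "C": "S", "D": "?", "E": "S",
            "F": "S", "G": "H", "H": "S", "I": "?", "J": "A",
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
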