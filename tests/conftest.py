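import pytest

from rpdselect import figure1_tree, score_all

# Printed score table of the six-leaf worked example, at presentation
# precision (3 decimals): leaf -> (height, brpd, urpd, n_branches)
EXAMPLE_TABLE = {
    "A": (7.000, 3.567, 3.250, 4),
    "B": (6.000, 2.567, 2.250, 4),
    "C": (6.000, 3.067, 3.500, 3),
    "D": (7.000, 3.900, 4.000, 3),
    "E": (6.000, 2.900, 3.000, 3),
    "F": (6.000, 6.000, 6.000, 1),
}


@pytest.fixture(scope="session")
def example_tree():
    return figure1_tree()


@pytest.fixture(scope="session")
def example_scores(example_tree):
    return score_all(example_tree)
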