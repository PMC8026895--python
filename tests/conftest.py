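import numpy as np
import pytest

from genoclust import LabeledMatrix


@pytest.fixture
def chain_matrix():
    """Three genomes where a–b and b–c exceed a 95% cutoff but a–c does not.

    The canonical component-vs-clique case: one component {a,b,c}, two
    overlapping cliques {a,b} and {b,c}.
    """
    labels = ("a", "b", "c")
    values = np.array(
        [
            [100.0, 96.0, 93.0],
            [96.0, 100.0, 96.0],
            [93.0, 96.0, 100.0],
        ]
    )
    return LabeledMatrix(labels, values, kind="identity", scale="percent")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
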