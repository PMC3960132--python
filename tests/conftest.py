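import numpy as np
import pytest

from middenid.trees import Tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tree(labels, rng) -> Tree:
    """Random unrooted binary topology by random stepwise insertion."""
    labels = list(labels)
    t = Tree.star(labels[:3])
    for lf in labels[3:]:
        edges = t.edges()
        t = t.insert_leaf(lf, edges[rng.integers(len(edges))])
    return t
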