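import numpy as np
import pytest

import coraldepth as cd


@pytest.fixture(scope="session")
def small_tree():
    """An 8-tip ultrametric birth-death tree shared across fast tests."""
    return cd.simulate_tree(8, 0.2, 0.05, seed=42)


@pytest.fixture(scope="session")
def medium_tree():
    return cd.simulate_tree(80, 0.08, 0.02, seed=13)


@pytest.fixture(scope="session")
def chain_tree():
    """root -> x (1 Ma) -> tip (2 Ma): a two-branch chain plus a sister tip.

    Built by hand so path-wise distances are known exactly.
    """
    # post-order ids: 0 = tip A (below x), 1 = sister tip B, 2 = x, 3 = root
    parent = [2, 3, 3, -1]
    length = [2.0, 3.0, 1.0, 0.0]
    labels = ["A", "B", None, None]
    return cd.TimeTree(parent, length, labels)
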