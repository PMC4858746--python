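import numpy as np
import pytest

import mimevol as mv


@pytest.fixture(scope="session")
def yule50():
    return mv.simulate_yule_tree(50, 0.05, seed=11)


@pytest.fixture(scope="session")
def yule50_traits(yule50):
    model = mv.PartitionModel([mv.RateMatrix2(0.01, 0.05)])
    traits, cmap = mv.simulate_discrete_history(yule50, model, 0.0, seed=12)
    return traits, cmap, model


def star_tree(n_tips: int, branch_length: float) -> mv.Tree:
    """Polytomy root with n identical terminal branches."""
    n = n_tips + 1
    parent = np.full(n, -1, dtype=np.int64)
    parent[:n_tips] = n_tips
    children = [[] for _ in range(n)]
    children[n_tips] = list(range(n_tips))
    blen = np.zeros(n)
    blen[:n_tips] = branch_length
    labels = [f"t{i}" for i in range(n_tips)] + [None]
    return mv.Tree(parent, children, blen, labels, n_tips)


@pytest.fixture(scope="session")
def small_biogeo():
    return mv.simulate_virtual_biogeography(
        n_model=10, n_other=15, b_model=2.0, seed=7
    )
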