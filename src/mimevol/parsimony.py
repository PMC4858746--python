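"""Fitch/Hartigan parsimony for the binary color character.

Serves as the rate-model-free cross-check of the likelihood
reconstructions: the minimum change count accommodates arbitrary rate
heterogeneity across clades. Polytomies are handled by Hartigan's
generalization (state sets chosen by majority vote among children), which
is exact for any number of children.
"""

from __future__ import annotations

import numpy as np

from .trees import Tree, TreeError

__all__ = ["fitch_parsimony"]


def fitch_parsimony(tree: Tree, traits: dict):
    """Minimum number of state changes plus one most-parsimonious labeling.

    Returns ``(n_changes, node_states)`` where ``node_states`` is an int
    array over all nodes giving one deterministic most-parsimonious
    assignment (ties broken toward state 0, then toward the parent state
    in the top-down pass).
    """
    n = tree.n_nodes
    # bottom-up (Hartigan): per node, count of children voting for each state
    upper = [None] * n  # set of states in the optimal set VU
    lower = [None] * n  # states in VL (second-best, Hartigan's VL)
    cost = 0
    for v in tree.postorder().tolist():
        if v < tree.n_tips:
            lbl = tree.labels[v]
            if lbl not in traits:
                raise TreeError(f"missing trait state for tip {lbl!r}")
            st = int(traits[lbl])
            if st not in (0, 1):
                raise ValueError(f"tip {lbl!r} state must be binary")
            upper[v] = {st}
            lower[v] = set()
            continue
        votes = [0, 0]
        for c in tree.children[v]:
            for s in upper[c]:
                votes[s] += 1
        k = max(votes)
        vu = {s for s in (0, 1) if votes[s] == k}
        vl = {s for s in (0, 1) if votes[s] == k - 1}
        upper[v] = vu
        lower[v] = vl
        cost += len(tree.children[v]) - k
    # top-down: pick states deterministically
    states = np.zeros(n, dtype=np.int64)
    for v in tree.preorder().tolist():
        p = tree.parent[v]
        if p < 0:
            states[v] = min(upper[v])
        else:
            ps = states[p]
            states[v] = ps if ps in upper[v] else min(upper[v])
    return cost, states
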