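"""Synthetic trees, trait histories and latitudes with known ground truth.

These generators stand in for the empirical inputs (a fixed time-scaled
snake phylogeny, observed color-pattern states, range midpoints) so every
downstream stage can be validated against planted parameters. All
randomness flows through explicit seeds; no global state is touched.
"""

from __future__ import annotations

import numpy as np

from .charmap import CharacterMap
from .mk import PartitionModel
from .trees import Tree

__all__ = [
    "simulate_yule_tree",
    "simulate_discrete_history",
    "simulate_bm_latitude",
]


def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int) -> Tree:
    """Pure-birth (Yule) tree with ``n_tips`` tips, branch lengths in Myr.

    A minimal time-scaled tree source: lineages split at rate
    ``birth_rate`` each; all pending branches are extended to the final
    speciation time so the tree is ultrametric. Deterministic per seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be at least 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    # grow the tree as an edge list keyed by lineage names; two lineages
    # descend from the root at time 0, each split replaces one active
    # lineage by two new ones
    edges = []  # (parent_key, child_key, start_time, end_time)
    active = [("L0", "root", 0.0), ("L1", "root", 0.0)]  # (key, parent, start)
    t = 0.0
    counter = 2
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        key, parent, start = active.pop(i)
        edges.append((parent, key, start, t))
        for _ in range(2):
            active.append((f"L{counter}", key, t))
            counter += 1
    # extend all pending branches to the next (unrealized) speciation time
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    tip_edges = [(parent, key, start, t_end) for key, parent, start in active]

    # assemble node ids: tips first, internals after, root last
    internal_keys = ["root"] + [e[1] for e in edges]
    tip_keys = [e[1] for e in tip_edges]
    n_int = len(internal_keys)
    n = len(tip_keys) + n_int
    idx = {}
    for i, k in enumerate(tip_keys):
        idx[k] = i
    order = internal_keys[1:] + ["root"]  # root last
    for j, k in enumerate(order):
        idx[k] = len(tip_keys) + j
    parent = np.full(n, -1, dtype=np.int64)
    children = [[] for _ in range(n)]
    blen = np.zeros(n)
    labels = [None] * n
    for pk, ck, s, e in edges + tip_edges:
        p, c = idx[pk], idx[ck]
        parent[c] = p
        children[p].append(c)
        blen[c] = e - s
    for i in range(len(tip_keys)):
        labels[i] = f"t{i + 1}"
    return Tree(parent, children, blen, labels, len(tip_keys))


def simulate_discrete_history(
    tree: Tree,
    model: PartitionModel,
    root_state_prob: float,
    seed: int,
):
    """Forward simulation of the binary trait: exact exponential waiting times.

    ``root_state_prob`` is the probability the root starts in state 1.
    Returns ``(traits, charmap)`` where the map's terminal states are, by
    construction, the returned tip states.
    """
    if not 0.0 <= root_state_prob <= 1.0:
        raise ValueError("root_state_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    assign = model.assignment(tree)
    rates = model.rates_array()
    root_state = int(rng.random() < root_state_prob)
    cmap = CharacterMap(tree, root_state, {})
    node_state = np.zeros(tree.n_nodes, dtype=np.int64)
    node_state[tree.root] = root_state
    for v in tree.preorder().tolist():
        if v == tree.root:
            continue
        s = int(node_state[tree.parent[v]])
        t, bl = 0.0, float(tree.branch_length[v])
        q01, q10 = rates[assign[v]]
        ev = []
        while True:
            rate = q01 if s == 0 else q10
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= bl:
                break
            s = 1 - s
            ev.append((t, s))
        if ev:
            cmap.events[v] = ev
        node_state[v] = s
    traits = {lbl: int(node_state[i]) for i, lbl in enumerate(tree.tip_labels)}
    return traits, cmap


def simulate_bm_latitude(
    tree: Tree,
    root_value: float,
    sigma2: float,
    seed: int,
    clade_sigma2: "dict | None" = None,
) -> dict:
    """Brownian-motion latitudes: increment ~ Normal(0, sigma2 * branch length).

    Returns node id -> value for every node (root included), so internal
    ground truth is available for reconstruction-recovery tests.
    ``clade_sigma2`` optionally maps a node id to a different rate for its
    stem branch and subtree (multi-rate extension).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    s2 = np.full(tree.n_nodes, float(sigma2))
    if clade_sigma2:
        for v in tree.preorder().tolist():
            p = tree.parent[v]
            inherited = sigma2 if p < 0 else s2[p]
            s2[v] = clade_sigma2.get(int(v), inherited)
    values = {tree.root: float(root_value)}
    for v in tree.preorder().tolist():
        if v == tree.root:
            continue
        sd = np.sqrt(s2[v] * tree.branch_length[v])
        values[int(v)] = values[int(tree.parent[v])] + float(rng.normal(0.0, sd))
    return values


def tip_latitudes(tree: Tree, node_values: dict) -> dict:
    """Project a node-value map onto tip labels."""
    return {lbl: node_values[i] for i, lbl in enumerate(tree.tip_labels)}
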