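"""Piecewise-constant character histories on a tree.

A :class:`CharacterMap` records, for every branch, the state at the start
of the branch (the parent-node state) plus an ordered list of timed change
events ``(time_from_parent, new_state)``. It is the common currency between
the forward trait simulator and the posterior stochastic-mapping sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import Tree

__all__ = ["CharacterMap", "CharacterMapError"]


class CharacterMapError(ValueError):
    pass


@dataclass
class CharacterMap:
    """Full binary-trait history on a tree.

    Attributes
    ----------
    tree : Tree
    root_state : int
    events : dict
        ``node id -> list of (t, new_state)`` for the branch above the node;
        times are measured from the parent node and strictly increase.
    """

    tree: Tree
    root_state: int
    events: dict = field(default_factory=dict)

    def branch_start_state(self, node: int) -> int:
        p = self.tree.parent[node]
        return self.root_state if p < 0 else self.branch_end_state(p)

    def branch_end_state(self, node: int) -> int:
        if node == self.tree.root:
            return self.root_state
        ev = self.events.get(node, [])
        return ev[-1][1] if ev else self.branch_start_state(node)

    def node_states(self) -> np.ndarray:
        """State at every node (branch-end state)."""
        s = np.zeros(self.tree.n_nodes, dtype=np.int64)
        for v in self.tree.preorder():
            if v == self.tree.root:
                s[v] = self.root_state
            else:
                ev = self.events.get(v, [])
                s[v] = ev[-1][1] if ev else s[self.tree.parent[v]]
        return s

    def tip_states(self) -> dict:
        s = self.node_states()
        return {lbl: int(s[i]) for i, lbl in enumerate(self.tree.tip_labels)}

    def n_events(self) -> int:
        return sum(len(v) for v in self.events.values())

    def branch_gain_loss(self, node: int) -> tuple:
        """(gains, losses) on the branch above ``node``."""
        gains = losses = 0
        for _, s in self.events.get(node, []):
            if s == 1:
                gains += 1
            else:
                losses += 1
        return gains, losses

    def total_gains_losses(self) -> tuple:
        g = l = 0
        for v in self.events:
            gv, lv = self.branch_gain_loss(v)
            g, l = g + gv, l + lv
        return g, l

    def state_at(self, node: int, t: float) -> int:
        """State on the branch above ``node`` at time ``t`` from the parent."""
        s = self.branch_start_state(node)
        for et, es in self.events.get(node, []):
            if et <= t:
                s = es
            else:
                break
        return s

    def validate(self) -> None:
        """Check internal consistency; raise CharacterMapError on violation."""
        states = self.node_states()
        for v, ev in self.events.items():
            if v == self.tree.root and ev:
                raise CharacterMapError("root carries no branch")
            bl = self.tree.branch_length[v]
            prev_t = 0.0
            s = self.branch_start_state(v)
            for t, ns in ev:
                if not (prev_t < t or (prev_t == 0.0 and t > 0.0)):
                    if t <= prev_t:
                        raise CharacterMapError(
                            f"event times not strictly increasing on branch {v}"
                        )
                if t > bl + 1e-9:
                    raise CharacterMapError(f"event beyond branch length on {v}")
                if ns == s:
                    raise CharacterMapError(f"non-alternating states on branch {v}")
                prev_t, s = t, ns
            if s != states[v]:
                raise CharacterMapError(f"end-state mismatch on branch {v}")
        # parent/child continuity is implied by construction of node_states()
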