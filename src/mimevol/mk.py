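"""Two-state Mk model: transition probabilities and pruning likelihood.

The color-pattern character is binary (0 = cryptic, 1 = red-black banded).
Evolution on each branch follows a continuous-time Markov chain with
instantaneous gain rate ``q01`` and loss rate ``q10`` (per Myr). Different
parts of the tree may evolve under different rate matrices; the
:class:`PartitionModel` maps every branch to one matrix via clade-rooted
shift points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .trees import Tree, TreeError

__all__ = [
    "RateMatrix2",
    "PartitionModel",
    "mk_transition_matrix",
    "tree_loglik",
    "fit_rates_ml",
    "whole_tree_symmetric_rate",
    "MLFit",
]

RATE_LO, RATE_HI = 1e-8, 1e3  # optimization bounds, per Myr


@dataclass(frozen=True)
class RateMatrix2:
    """Gain (q01) and loss (q10) rates of the binary trait, per Myr."""

    q01: float
    q10: float

    def __post_init__(self):
        if not (math.isfinite(self.q01) and math.isfinite(self.q10)):
            raise ValueError("rates must be finite")
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be non-negative")

    @property
    def stationary_pi1(self) -> float:
        s = self.q01 + self.q10
        return self.q01 / s if s > 0 else 0.5


@dataclass
class PartitionModel:
    """Clade-indexed set of 2-state rate matrices.

    ``shift_nodes`` maps an internal node id to a matrix index; the new
    matrix governs every branch strictly inside that node's subtree
    (crown branches — the shift node's own stem stays with its parent's
    partition), unless overridden by a nested shift. Matrix 0 is the
    background (root) partition.
    """

    matrices: list
    shift_nodes: dict = field(default_factory=dict)

    def __post_init__(self):
        used = sorted(set(self.shift_nodes.values()) | {0})
        if used != list(range(len(self.matrices))):
            raise ValueError("matrix indices must be contiguous and all used")

    @property
    def n_matrices(self) -> int:
        return len(self.matrices)

    @property
    def n_parameters(self) -> int:
        """2 rates per matrix plus one location parameter per shift."""
        m = self.n_matrices
        return 2 * m + (m - 1)

    def assignment(self, tree: Tree) -> np.ndarray:
        """Matrix index for the branch above every node.

        The entry for the root gives the partition the root itself sits
        in (used for the root prior). Crown semantics: the branch above
        node c follows the partition of c's parent.
        """
        part = np.zeros(tree.n_nodes, dtype=np.int64)  # node partitions
        for v in tree.preorder():
            p = tree.parent[v]
            inherited = 0 if p < 0 else part[p]
            part[v] = self.shift_nodes.get(int(v), inherited)
        a = np.zeros(tree.n_nodes, dtype=np.int64)
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            a[v] = part[v] if p < 0 else part[p]
        return a

    def with_rates(self, rates: np.ndarray) -> "PartitionModel":
        """Copy with matrix rates replaced by ``rates`` (shape (m, 2))."""
        mats = [RateMatrix2(float(q01), float(q10)) for q01, q10 in rates]
        return PartitionModel(mats, dict(self.shift_nodes))

    def rates_array(self) -> np.ndarray:
        return np.array([[m.q01, m.q10] for m in self.matrices])


def mk_transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """Closed-form 2x2 transition probability matrix P(t).

    P(t) = Pi + (I - Pi) * exp(-(q01+q10) t) with stationary rows
    Pi = [[pi0, pi1], [pi0, pi1]], pi1 = q01/(q01+q10). For q01=q10=0 the
    matrix is the identity.
    """
    if q01 < 0 or q10 < 0 or t < 0:
        raise ValueError("rates and time must be non-negative")
    s = q01 + q10
    if s == 0:
        return np.eye(2)
    pi1 = q01 / s
    pi0 = 1.0 - pi1
    e = math.exp(-s * t)
    return np.array(
        [
            [pi0 + pi1 * e, pi1 * (1.0 - e)],
            [pi0 * (1.0 - e), pi1 + pi0 * e],
        ]
    )


def _branch_probs(tree: Tree, model: PartitionModel, assignment: np.ndarray):
    """Vectorized per-branch transition probabilities (p00, p01, p10, p11)."""
    rates = model.rates_array()
    q01 = rates[assignment, 0]
    q10 = rates[assignment, 1]
    t = tree.branch_length
    s = q01 + q10
    with np.errstate(divide="ignore", invalid="ignore"):
        pi1 = np.where(s > 0, q01 / np.where(s > 0, s, 1.0), 0.5)
    pi0 = 1.0 - pi1
    e = np.exp(-s * t)
    return pi0 + pi1 * e, pi1 * (1.0 - e), pi0 * (1.0 - e), pi1 + pi0 * e


def _tip_state_array(tree: Tree, traits: dict) -> np.ndarray:
    states = np.empty(tree.n_tips, dtype=np.int64)
    for i, lbl in enumerate(tree.tip_labels):
        if lbl not in traits:
            raise TreeError(f"missing trait state for tip {lbl!r}")
        st = int(traits[lbl])
        if st not in (0, 1):
            raise ValueError(f"state for tip {lbl!r} must be 0 or 1")
        states[i] = st
    return states


def tree_loglik(
    tree: Tree,
    traits: dict,
    model: PartitionModel,
    root: "str | float" = "stationary",
) -> float:
    """Log-likelihood of binary tip data by Felsenstein's pruning algorithm.

    Parameters
    ----------
    traits : dict
        Tip label -> state in {0, 1}; must cover every tip.
    root : "stationary" or float
        Root handling: stationary frequencies of the root partition's
        matrix (default) or a fixed prior probability of state 1.
    """
    assignment = model.assignment(tree)
    p00, p01, p10, p11 = _branch_probs(tree, model, assignment)
    states = _tip_state_array(tree, traits)

    n = tree.n_nodes
    L0 = [0.0] * n
    L1 = [0.0] * n
    p00l, p01l, p10l, p11l = p00.tolist(), p01.tolist(), p10.tolist(), p11.tolist()
    logscale = 0.0
    for v in tree.postorder().tolist():
        if v < tree.n_tips:
            st = states[v]
            L0[v] = 1.0 - st
            L1[v] = float(st)
            continue
        l0 = l1 = 1.0
        for c in tree.children[v]:
            l0 *= p00l[c] * L0[c] + p01l[c] * L1[c]
            l1 *= p10l[c] * L0[c] + p11l[c] * L1[c]
        m = l0 if l0 > l1 else l1
        if m <= 0.0:
            return -math.inf
        L0[v] = l0 / m
        L1[v] = l1 / m
        logscale += math.log(m)

    r = tree.root
    if root == "stationary":
        pi1 = model.matrices[int(assignment[r])].stationary_pi1
    else:
        pi1 = float(root)
        if not 0.0 <= pi1 <= 1.0:
            raise ValueError("fixed root prior must be in [0, 1]")
    lik = (1.0 - pi1) * L0[r] + pi1 * L1[r]
    if lik <= 0.0:
        return -math.inf
    return math.log(lik) + logscale


@dataclass
class MLFit:
    model: PartitionModel
    loglik: float
    n_starts_used: int

    @property
    def aic(self) -> float:
        return 2.0 * self.model.n_parameters - 2.0 * self.loglik


def _heuristic_rate(tree: Tree, traits: dict) -> float:
    """Crude initial rate: parsimony change count / total tree length."""
    from .parsimony import fitch_parsimony

    changes, _ = fitch_parsimony(tree, traits)
    tl = tree.total_branch_length()
    return max(changes, 1) / max(tl, 1e-9)


def fit_rates_ml(
    tree: Tree,
    traits: dict,
    model: PartitionModel,
    root: "str | float" = "stationary",
    free: "list | None" = None,
    n_starts: int = 3,
    seed: int = 0,
) -> MLFit:
    """Maximize the pruning likelihood over (log) transition rates.

    The partition assignment is held fixed; only rates move. ``free``
    restricts optimization to the listed matrix indices (others stay at
    their current values). Bounded quasi-Newton in log-rate space with
    multi-start to dodge local optima.
    """
    if free is None:
        free = list(range(model.n_matrices))
    rates0 = model.rates_array()
    rng = np.random.default_rng(seed)
    lo, hi = math.log(RATE_LO), math.log(RATE_HI)

    def unpack(x):
        rates = rates0.copy()
        rates[free, :] = np.exp(x.reshape(len(free), 2))
        return rates

    def nll(x):
        m = model.with_rates(unpack(x))
        return -tree_loglik(tree, traits, m, root=root)

    base = _heuristic_rate(tree, traits)
    x0 = np.full(2 * len(free), math.log(max(base, RATE_LO * 10)))
    # deterministic spread over rate scales first, random jitter after
    starts = [x0 + math.log(f) for f in (1.0, 10.0, 0.1)][:n_starts]
    for _ in range(n_starts - len(starts)):
        starts.append(np.clip(x0 + rng.normal(0, 1.5, size=len(x0)), lo, hi))

    best = None
    n_ok = 0
    for x0 in starts:
        res = minimize(
            nll,
            np.clip(x0, lo, hi),
            method="L-BFGS-B",
            bounds=[(lo, hi)] * (2 * len(free)),
        )
        if not np.isfinite(res.fun):
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("rate optimization failed in all starts")
    return MLFit(model.with_rates(unpack(best.x)), -float(best.fun), n_ok)


def whole_tree_symmetric_rate(
    tree: Tree, traits: dict, root: "str | float" = "stationary"
) -> float:
    """MLE of the single symmetric rate r under q01 = q10 = r.

    Used to center the exponential rate prior for Bayesian estimation
    (prior mean = 10 x this rate). If all tips share one state the MLE
    sits at the lower optimization bound.
    """
    lo, hi = math.log(RATE_LO), math.log(RATE_HI)

    def nll(logr):
        r = math.exp(logr)
        m = PartitionModel([RateMatrix2(r, r)])
        return -tree_loglik(tree, traits, m, root=root)

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(math.exp(res.x))
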