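"""Stepwise-AIC search for clade-specific transition-rate partitions.

Starting from a single rate matrix fit to the whole tree, the search
repeatedly tries to decouple one subclade: every internal node with at
least ``min_descendants`` descendant tips is a candidate shift point, the
candidate model adds a fresh (q01, q10) matrix on that clade, and the best
candidate is accepted when it improves AIC by more than ``delta_aic``.
Each added matrix costs 2 rate parameters plus 1 location parameter, so an
m-matrix model has k = 2m + (m - 1). Accepted shift locations are frozen;
rates of all matrices are re-optimized jointly after each acceptance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .mk import (
    MLFit,
    PartitionModel,
    RATE_HI,
    RATE_LO,
    RateMatrix2,
    _branch_probs,
    _tip_state_array,
    fit_rates_ml,
)
from .trees import Tree

__all__ = ["stepwise_partition_search", "PartitionSearchResult"]


@dataclass
class PartitionSearchResult:
    model: PartitionModel
    loglik: float
    aic: float
    trace: list = field(default_factory=list)  # dicts: step, k, lnL, AIC, ...
    stopping_reason: str = ""

    def trace_table(self):
        import pandas as pd

        return pd.DataFrame(self.trace)


class _ScanCache:
    """Shared quantities for scoring crown-shift candidates quickly.

    For the incumbent model (rates fixed), the full-tree likelihood
    decomposes at any node v as  L = Σ_i O_i(v) · L_i(v)  (up to tracked
    log scales), where L(v) is the inner partial of v's subtree and O(v)
    the outer conditional including v's stem branch. Both are computed
    once per scan step; scoring a candidate crown then only recomputes
    the partials inside that candidate's subtree.
    """

    def __init__(self, tree: Tree, traits: dict, model: PartitionModel,
                 root: "str | float"):
        self.tree = tree
        self.states = _tip_state_array(tree, traits)
        assignment = model.assignment(tree)
        p = _branch_probs(tree, model, assignment)
        self.p00, self.p01, self.p10, self.p11 = p
        n = tree.n_nodes
        # inner partials with per-node accumulated log scale
        L = np.zeros((n, 2))
        S = np.zeros(n)
        for v in tree.postorder().tolist():
            if v < tree.n_tips:
                L[v, self.states[v]] = 1.0
                continue
            l0 = l1 = 1.0
            s = 0.0
            for c in tree.children[v]:
                m0 = self.p00[c] * L[c, 0] + self.p01[c] * L[c, 1]
                m1 = self.p10[c] * L[c, 0] + self.p11[c] * L[c, 1]
                l0 *= m0
                l1 *= m1
                s += S[c]
            mx = max(l0, l1)
            if mx <= 0:
                raise ValueError("zero likelihood under incumbent model")
            L[v] = (l0 / mx, l1 / mx)
            S[v] = s + math.log(mx)
        self.L, self.S = L, S
        if root == "stationary":
            pi1 = model.matrices[int(assignment[tree.root])].stationary_pi1
        else:
            pi1 = float(root)
        # outer conditionals O with their own log scale T
        O = np.zeros((n, 2))
        T = np.zeros(n)
        r = tree.root
        O[r] = (1.0 - pi1, pi1)
        for u in tree.preorder().tolist():
            kids = tree.children[u]
            for c in kids:
                w0 = O[u, 0]
                w1 = O[u, 1]
                t = T[u]
                for s_ in kids:
                    if s_ == c:
                        continue
                    w0 *= self.p00[s_] * L[s_, 0] + self.p01[s_] * L[s_, 1]
                    w1 *= self.p10[s_] * L[s_, 0] + self.p11[s_] * L[s_, 1]
                    t += S[s_]
                o0 = w0 * self.p00[c] + w1 * self.p10[c]
                o1 = w0 * self.p01[c] + w1 * self.p11[c]
                mx = max(o0, o1)
                if mx > 0:
                    O[c] = (o0 / mx, o1 / mx)
                    T[c] = t + math.log(mx)
                else:
                    O[c] = (0.0, 0.0)
                    T[c] = t
        self.O, self.T = O, T
        self.loglik = self._combine(r, L[r], S[r], outer_is_root=True,
                                    pi=(1.0 - pi1, pi1))

    def _combine(self, v, Lv, Sv, outer_is_root=False, pi=None):
        if outer_is_root:
            lik = pi[0] * Lv[0] + pi[1] * Lv[1]
            return math.log(lik) + Sv
        lik = self.O[v, 0] * Lv[0] + self.O[v, 1] * Lv[1]
        if lik <= 0:
            return -math.inf
        return math.log(lik) + self.T[v] + Sv

    def crown_loglik(self, v: int, q01: float, q10: float) -> float:
        """Full-tree lnL with branches strictly below v at (q01, q10)."""
        tree = self.tree
        order = tree.subtree_nodes(v)[::-1]  # children before parents
        s = q01 + q10
        pi1 = q01 / s if s > 0 else 0.5
        pi0 = 1.0 - pi1
        L = {}
        Sl = {}
        for w in order.tolist():
            if w < tree.n_tips:
                st = self.states[w]
                L[w] = (1.0 - st, float(st))
                Sl[w] = 0.0
                continue
            l0 = l1 = 1.0
            sc = 0.0
            for c in tree.children[w]:
                e = math.exp(-s * tree.branch_length[c]) if s > 0 else 1.0
                c00 = pi0 + pi1 * e
                c01 = pi1 * (1.0 - e)
                c10 = pi0 * (1.0 - e)
                c11 = pi1 + pi0 * e
                lc = L[c]
                l0 *= c00 * lc[0] + c01 * lc[1]
                l1 *= c10 * lc[0] + c11 * lc[1]
                sc += Sl[c]
            mx = l0 if l0 > l1 else l1
            if mx <= 0:
                return -math.inf
            L[w] = (l0 / mx, l1 / mx)
            Sl[w] = sc + math.log(mx)
        return self._combine(int(v), L[int(v)], Sl[int(v)])

    def fit_crown(self, v: int, start_rates, n_starts: int = 2):
        """Maximize crown_loglik over the candidate matrix's log-rates."""
        lo, hi = math.log(RATE_LO), math.log(RATE_HI)
        x0 = np.log(np.clip(start_rates, RATE_LO * 10, RATE_HI))
        starts = [x0, np.clip(x0 + math.log(10.0), lo, hi)][:n_starts]

        def nll(x):
            return -self.crown_loglik(v, math.exp(x[0]), math.exp(x[1]))

        best = None
        for st in starts:
            res = minimize(nll, st, method="L-BFGS-B", bounds=[(lo, hi)] * 2)
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError(f"crown fit failed at node {v}")
        return float(-best.fun), (math.exp(best.x[0]), math.exp(best.x[1]))


def _candidate_nodes(tree: Tree, min_descendants: int, taken) -> list:
    cnt = tree.n_descendant_tips()
    out = []
    for v in range(tree.n_tips, tree.n_nodes):
        if v == tree.root or v in taken:
            continue
        if cnt[v] >= min_descendants:
            out.append(v)
    return out


def stepwise_partition_search(
    tree: Tree,
    traits: dict,
    min_descendants: int = 5,
    delta_aic: float = 2.0,
    root: "str | float" = "stationary",
    max_matrices: "int | None" = None,
    scan_starts: int = 2,
    refit_starts: int = 3,
    seed: int = 0,
) -> PartitionSearchResult:
    """Greedy forward selection of rate-shift locations by AIC.

    At each step, candidate shifts are scored by optimizing only the new
    matrix's rates (background rates fixed at the incumbent MLE); the best
    candidate is accepted if its AIC beats the incumbent by more than
    ``delta_aic``, after which all rates are re-optimized jointly. The
    full per-step AIC trace is returned.
    """
    if tree.n_tips < min_descendants:
        raise ValueError("tree smaller than the clade-size threshold")
    base = PartitionModel([RateMatrix2(0.1, 0.1)])
    fit = fit_rates_ml(tree, traits, base, root=root, n_starts=refit_starts, seed=seed)
    trace = [
        {
            "step": 0,
            "n_matrices": 1,
            "k": fit.model.n_parameters,
            "loglik": fit.loglik,
            "aic": fit.aic,
            "delta_aic": np.nan,
            "shift_node": None,
            "accepted": True,
        }
    ]
    current = fit
    reason = "no further improvement"
    step = 0
    while True:
        step += 1
        m = current.model.n_matrices
        if max_matrices is not None and m >= max_matrices:
            reason = "matrix cap reached"
            break
        cands = _candidate_nodes(tree, min_descendants, set(current.model.shift_nodes))
        if not cands:
            reason = "no candidate shift nodes left"
            break
        cache = _ScanCache(tree, traits, current.model, root)
        start_rates = current.model.rates_array()[0]
        best_cand, best_fit = None, None
        for v in cands:
            shifts = dict(current.model.shift_nodes)
            shifts[int(v)] = m
            nested = any(
                s != v and s in tree.subtree_nodes(v)
                for s in current.model.shift_nodes
            )
            try:
                if nested:
                    cand_model = PartitionModel(
                        list(current.model.matrices) + [current.model.matrices[0]],
                        shifts,
                    )
                    cfit = fit_rates_ml(
                        tree, traits, cand_model, root=root, free=[m],
                        n_starts=scan_starts, seed=seed + v,
                    )
                else:
                    lnl, (q01, q10) = cache.fit_crown(
                        int(v), start_rates, n_starts=scan_starts
                    )
                    cand_model = PartitionModel(
                        list(current.model.matrices) + [RateMatrix2(q01, q10)],
                        shifts,
                    )
                    cfit = MLFit(cand_model, lnl, scan_starts)
            except RuntimeError:
                continue  # recorded as a skipped candidate
            if best_fit is None or cfit.aic < best_fit.aic:
                best_cand, best_fit = v, cfit
        if best_fit is None or current.aic - best_fit.aic <= delta_aic:
            reason = "no candidate improved AIC by more than the threshold"
            break
        # accept: joint refit of all rates at the frozen shift locations
        refit = fit_rates_ml(
            tree, traits, best_fit.model, root=root,
            n_starts=refit_starts, seed=seed + step,
        )
        if refit.loglik < best_fit.loglik:  # joint refit must not be worse
            refit = best_fit
        trace.append(
            {
                "step": step,
                "n_matrices": refit.model.n_matrices,
                "k": refit.model.n_parameters,
                "loglik": refit.loglik,
                "aic": refit.aic,
                "delta_aic": current.aic - refit.aic,
                "shift_node": int(best_cand),
                "accepted": True,
            }
        )
        current = refit
    return PartitionSearchResult(
        model=current.model,
        loglik=current.loglik,
        aic=current.aic,
        trace=trace,
        stopping_reason=reason,
    )
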