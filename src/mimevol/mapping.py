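"""Bayesian rates and stochastic character mapping.

Shift locations come from the stepwise-AIC search and are held fixed; rate
parameters on the partitions get a Bayesian treatment (exponential priors
centered at 10x the whole-tree symmetric ML rate, Metropolis-Hastings on
log-rates). Posterior draws feed stochastic character maps: node states are
sampled top-down from conditional likelihoods and branch histories are
drawn exactly, conditioned on both endpoint states, by uniformization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .charmap import CharacterMap
from .mk import PartitionModel, _branch_probs, _tip_state_array, tree_loglik, whole_tree_symmetric_rate
from .trees import Tree

__all__ = [
    "PriorSpec",
    "RatePosterior",
    "MapEnsemble",
    "mcmc_rates",
    "sample_stochastic_map",
    "sample_map_ensemble",
    "summarize_ensemble",
]


@dataclass
class PriorSpec:
    """Exponential rate prior + root-state prior for the mapping stage.

    ``mean`` is the exponential prior mean shared by all rate parameters,
    conventionally ``multiplier`` (default 10) times the whole-tree
    symmetric ML rate. ``root_prior`` is either "stationary" or a fixed
    prior probability of state 1 at the root (the empirical analysis used
    0.05).
    """

    mean: float
    root_prior: "str | float" = "stationary"
    multiplier: float = 10.0

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("prior mean must be positive")
        if isinstance(self.root_prior, float) and not 0 <= self.root_prior <= 1:
            raise ValueError("root prior must be in [0, 1]")

    @classmethod
    def from_whole_tree_rate(
        cls, tree: Tree, traits: dict, multiplier: float = 10.0,
        root_prior: "str | float" = "stationary",
    ) -> "PriorSpec":
        r = whole_tree_symmetric_rate(tree, traits)
        return cls(mean=multiplier * max(r, 1e-8), root_prior=root_prior,
                   multiplier=multiplier)


@dataclass
class RatePosterior:
    """Post burn-in, thinned MCMC samples of the partition rates."""

    samples: np.ndarray  # (n_stored, 2m): q01_0, q10_0, q01_1, ...
    param_names: list
    burn_in_fraction: float
    thin: int
    acceptance_rate: float
    ess: np.ndarray
    seed: int

    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        a = (1.0 - level) / 2.0
        return np.quantile(self.samples, [a, 1.0 - a], axis=0).T

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        i = int(rng.integers(len(self.samples)))
        return self.samples[i]


def _log_prior(logq: np.ndarray, mean: float) -> float:
    # exponential density on q, with log|dq/dlogq| = logq Jacobian
    q = np.exp(logq)
    return float(np.sum(logq - q / mean) - len(logq) * math.log(mean))


def mcmc_rates(
    tree: Tree,
    traits: dict,
    model: PartitionModel,
    prior: PriorSpec,
    n_steps: int = 20000,
    seed: int = 0,
    use_likelihood: bool = True,
    burn_in_fraction: float = 0.25,
    max_stored: int = 5000,
    ess_floor: float = 100.0,
) -> RatePosterior:
    """Metropolis-Hastings over log-rates of all partition matrices.

    Gaussian random-walk proposals, jointly on all 2m log-rates, with the
    step size adapted during burn-in toward 20-40% acceptance. Chains are
    reproducible given the seed. ``use_likelihood=False`` samples the
    prior alone (a validation mode: posterior means must then match the
    exponential prior mean).
    """
    import warnings

    rng = np.random.default_rng(seed)
    m = model.n_matrices
    d = 2 * m
    names = [f"{p}_{i}" for i in range(m) for p in ("q01", "q10")]

    def logpost(logq):
        lp = _log_prior(logq, prior.mean)
        if use_likelihood:
            mod = model.with_rates(np.exp(logq).reshape(m, 2))
            lp += tree_loglik(tree, traits, mod, root=prior.root_prior)
        return lp

    x = np.log(np.clip(model.rates_array().ravel(), 1e-6, None))
    lp = logpost(x)
    scale = 0.5
    burn = int(burn_in_fraction * n_steps)
    kept = []
    n_acc = 0
    acc_window = 0
    for step in range(n_steps):
        prop = x + rng.normal(0.0, scale, size=d)
        lpp = logpost(prop)
        if math.log(rng.random()) < lpp - lp:
            x, lp = prop, lpp
            n_acc += 1
            acc_window += 1
        if step < burn and (step + 1) % 100 == 0:
            rate = acc_window / 100.0
            if rate < 0.2:
                scale *= 0.7
            elif rate > 0.4:
                scale *= 1.3
            acc_window = 0
        if step >= burn:
            kept.append(np.exp(x))
    kept = np.asarray(kept)
    thin = max(1, int(math.ceil(len(kept) / max_stored)))
    kept = kept[::thin]
    ess = _ess(kept)
    if np.any(ess < ess_floor):
        warnings.warn(
            f"ESS below {ess_floor:g} for some rate parameters: {ess}",
            RuntimeWarning,
        )
    return RatePosterior(
        samples=kept,
        param_names=names,
        burn_in_fraction=burn_in_fraction,
        thin=thin,
        acceptance_rate=n_acc / n_steps,
        ess=ess,
        seed=seed,
    )


def _ess(samples: np.ndarray) -> np.ndarray:
    """Effective sample size per parameter (autocorrelation-time method)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz

        return np.array(
            [float(arviz.ess(samples[:, j])) for j in range(samples.shape[1])]
        )


# ----------------------------------------------------------------------
# conditional likelihoods and node-state sampling


def _postorder_partials(tree: Tree, traits: dict, model: PartitionModel):
    """Per-node scaled partial likelihoods (each row renormalized to sum 1)."""
    assignment = model.assignment(tree)
    p00, p01, p10, p11 = _branch_probs(tree, model, assignment)
    states = _tip_state_array(tree, traits)
    L = np.zeros((tree.n_nodes, 2))
    for v in tree.postorder().tolist():
        if v < tree.n_tips:
            L[v, states[v]] = 1.0
            continue
        l0 = l1 = 1.0
        for c in tree.children[v]:
            l0 *= p00[c] * L[c, 0] + p01[c] * L[c, 1]
            l1 *= p10[c] * L[c, 0] + p11[c] * L[c, 1]
        s = l0 + l1
        if s <= 0:
            raise ValueError("zero likelihood: data impossible under model")
        L[v] = (l0 / s, l1 / s)
    return L, assignment


def root_posterior(
    tree: Tree, traits: dict, model: PartitionModel,
    root: "str | float" = "stationary",
) -> np.ndarray:
    """Analytic root-state posterior: prior x root conditionals, normalized."""
    L, assignment = _postorder_partials(tree, traits, model)
    if root == "stationary":
        pi1 = model.matrices[int(assignment[tree.root])].stationary_pi1
    else:
        pi1 = float(root)
    w = np.array([(1.0 - pi1) * L[tree.root, 0], pi1 * L[tree.root, 1]])
    return w / w.sum()


# ----------------------------------------------------------------------
# endpoint-conditioned path sampling (uniformization)

_MAX_JUMPS = 10000


def _sample_bridge(q01, q10, t, a, b, rng):
    """Exact CTMC path on [0, t] conditioned on X(0)=a, X(t)=b.

    Uniformization: dominate the chain by a Poisson(mu*t) process of
    candidate jumps with mu = max(q01, q10), transition kernel
    R = I + Q/mu; sample the jump count from its conditional distribution,
    place jump times as uniform order statistics, sample the state ladder
    by forward filtering against powers of R, then discard virtual
    (self) transitions. Returns the event list [(time, new_state), ...].
    """
    mu = max(q01, q10)
    if mu <= 0.0:
        if a != b:
            raise ValueError("impossible endpoints under zero rates")
        return []
    Q = np.array([[-q01, q01], [q10, -q10]])
    R = np.eye(2) + Q / mu
    # transition probability P_ab(t), closed form
    s = q01 + q10
    pi1 = q01 / s
    e = math.exp(-s * t)
    P = np.array(
        [[1 - pi1 + pi1 * e, pi1 * (1 - e)],
         [(1 - pi1) * (1 - e), pi1 + (1 - pi1) * e]]
    )
    pab = P[a, b]
    if pab <= 0:
        raise ValueError("impossible endpoint pair")
    # conditional jump-count distribution
    u = rng.random() * pab
    Rpow = [np.eye(2)]
    logpois = -mu * t
    term = math.exp(logpois) * Rpow[0][a, b]
    acc = term
    n = 0
    while acc < u and n < _MAX_JUMPS:
        n += 1
        Rpow.append(Rpow[-1] @ R)
        logpois += math.log(mu * t) - math.log(n)
        acc += math.exp(logpois) * Rpow[n][a, b]
    if n == 0:
        return []
    times = np.sort(rng.random(n)) * t
    # forward sampling of the state ladder against R-power backward weights
    events = []
    cur = a
    for k in range(1, n + 1):
        back = Rpow[n - k]
        w = np.array([R[cur, 0] * back[0, b], R[cur, 1] * back[1, b]])
        nxt = int(rng.random() * w.sum() > w[0])
        if nxt != cur:
            events.append((float(times[k - 1]), nxt))
            cur = nxt
    return events


def sample_stochastic_map(
    tree: Tree,
    traits: dict,
    model: PartitionModel,
    root: "str | float" = "stationary",
    rng: "np.random.Generator | int" = 0,
) -> CharacterMap:
    """One stochastic character map conditioned on the observed tip states.

    Root state ~ (root prior x root conditionals); descendant node states
    sampled top-down in proportion to transition probability times the
    subtree conditional likelihood; branch histories by uniformization.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L, assignment = _postorder_partials(tree, traits, model)
    p00, p01, p10, p11 = _branch_probs(tree, model, assignment)
    rates = model.rates_array()

    if root == "stationary":
        pi1 = model.matrices[int(assignment[tree.root])].stationary_pi1
    else:
        pi1 = float(root)
    w = np.array([(1.0 - pi1) * L[tree.root, 0], pi1 * L[tree.root, 1]])
    node_state = np.zeros(tree.n_nodes, dtype=np.int64)
    node_state[tree.root] = int(rng.random() * w.sum() > w[0])
    for v in tree.preorder().tolist():
        if v == tree.root:
            continue
        i = node_state[tree.parent[v]]
        trans = (p00[v], p01[v]) if i == 0 else (p10[v], p11[v])
        wv = np.array([trans[0] * L[v, 0], trans[1] * L[v, 1]])
        node_state[v] = int(rng.random() * wv.sum() > wv[0])
    cmap = CharacterMap(tree, int(node_state[tree.root]), {})
    for v in tree.preorder().tolist():
        if v == tree.root:
            continue
        q01, q10 = rates[assignment[v]]
        ev = _sample_bridge(
            q01, q10, float(tree.branch_length[v]),
            int(node_state[tree.parent[v]]), int(node_state[v]), rng,
        )
        if ev:
            cmap.events[v] = ev
    return cmap


# ----------------------------------------------------------------------
# ensembles


@dataclass
class MapEnsemble:
    """A set of stochastic character maps ('pseudo-histories')."""

    maps: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.maps)

    @property
    def tree(self) -> Tree:
        return self.maps[0].tree

    def per_map_totals(self) -> np.ndarray:
        """(n_maps, 2) array of total (gains, losses) per map."""
        return np.array([m.total_gains_losses() for m in self.maps])


def sample_map_ensemble(
    tree: Tree,
    traits: dict,
    model: PartitionModel,
    posterior: "RatePosterior | None" = None,
    n_maps: int = 500,
    root: "str | float" = "stationary",
    seed: int = 0,
) -> MapEnsemble:
    """Draw ``n_maps`` stochastic maps.

    If a rate posterior is supplied, each map uses an independent rate
    draw (integrating over rate uncertainty, the hybrid ML/Bayesian
    design); otherwise the model's point rates are reused.
    """
    rng = np.random.default_rng(seed)
    maps = []
    m = model.n_matrices
    for _ in range(n_maps):
        mod = model
        if posterior is not None:
            mod = model.with_rates(posterior.draw(rng).reshape(m, 2))
        maps.append(sample_stochastic_map(tree, traits, mod, root=root, rng=rng))
    return MapEnsemble(maps)


@dataclass
class EnsembleSummary:
    times: np.ndarray            # absolute time from the root, Myr
    freq_state1: np.ndarray      # fraction of extant lineages in state 1
    branch_mean_gains: np.ndarray
    branch_mean_losses: np.ndarray
    credible_map_index: int
    credible_map: CharacterMap


def _lineage_sets(tree: Tree, times: np.ndarray):
    """For each time point, the node ids of lineages extant at that time."""
    h = tree.node_heights()
    out = []
    for t in times:
        lineages = []
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            if h[p] <= t < h[v] or (v < tree.n_tips and t >= h[v]):
                lineages.append(v)
        out.append(lineages)
    return out


def summarize_ensemble(ensemble: MapEnsemble, n_time: int = 1000) -> EnsembleSummary:
    """Frequency-through-time, per-branch event rates, credible configuration.

    The trait frequency at each of ``n_time`` equally spaced times is the
    fraction of lineages alive at that time assigned state 1, averaged
    over maps. The 'maximum credibility' configuration is the sampled map
    maximizing the sum over branches of the log marginal frequency of its
    per-branch (gains, losses) pair.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    tree = ensemble.tree
    h = tree.node_heights()
    times = np.linspace(0.0, tree.depth(), n_time)
    lineages = _lineage_sets(tree, times)
    freq = np.zeros(n_time)
    n_nodes = tree.n_nodes
    gains = np.zeros(n_nodes)
    losses = np.zeros(n_nodes)
    pair_counts = [dict() for _ in range(n_nodes)]
    for cmap in ensemble.maps:
        for ti, lin in enumerate(lineages):
            if not lin:
                continue
            s1 = 0
            for v in lin:
                tt = min(times[ti] - h[tree.parent[v]], tree.branch_length[v])
                s1 += cmap.state_at(v, tt)
            freq[ti] += s1 / len(lin)
        for v in range(n_nodes):
            if v == tree.root:
                continue
            g, l = cmap.branch_gain_loss(v)
            gains[v] += g
            losses[v] += l
            pair_counts[v][(g, l)] = pair_counts[v].get((g, l), 0) + 1
    n_maps = len(ensemble)
    freq /= n_maps
    gains /= n_maps
    losses /= n_maps
    # credible configuration
    best_i, best_score = 0, -math.inf
    for i, cmap in enumerate(ensemble.maps):
        score = 0.0
        for v in range(n_nodes):
            if v == tree.root:
                continue
            score += math.log(pair_counts[v][cmap.branch_gain_loss(v)] / n_maps)
        if score > best_score:
            best_i, best_score = i, score
    return EnsembleSummary(
        times=times,
        freq_state1=freq,
        branch_mean_gains=gains,
        branch_mean_losses=losses,
        credible_map_index=best_i,
        credible_map=ensemble.maps[best_i],
    )
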