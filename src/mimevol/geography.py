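"""Latitude and time of trait gains and losses.

Ancestral latitudinal midpoints are reconstructed under single-rate
Brownian motion by generalized least squares; every change event in a
stochastic-map ensemble is then placed at the linear interpolation
delta * s_x + (1 - delta) * s_y between the descendant (s_x) and parent
(s_y) node latitudes, where delta is the fractional position of the event
along its branch. Summaries: kernel density over latitude per event type,
time x latitude grids scaled to the joint maximum, tropical vs
north-temperate loss ratios, and a contrasts-based test of latitudinal
conservatism.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import MapEnsemble
from .trees import Tree, TreeError

logger = logging.getLogger(__name__)

__all__ = [
    "bm_ancestral_latitudes",
    "interpolate_event_latitude",
    "locate_events",
    "event_latitude_density",
    "time_latitude_grid",
    "zone_loss_ratio",
    "pic_conservatism",
    "phylogenetic_independent_contrasts",
    "ZoneRatio",
    "ConservatismResult",
]

TROPICS = (-23.0, 23.0)          # closed interval
NORTH_TEMPERATE = (23.0, 35.0)   # half-open (23, 35]


def _vcv_rows(tree: Tree):
    """Shared-path (MRCA height) matrix over all nodes, via descendant sets."""
    n = tree.n_nodes
    h = tree.node_heights()
    C = np.zeros((n, n))
    desc = [None] * n
    for v in tree.postorder().tolist():
        if v < tree.n_tips:
            desc[v] = {v}
        else:
            s = set()
            for c in tree.children[v]:
                s |= desc[c]
            desc[v] = s
        C[v, v] = h[v]
    # fill pairwise MRCA heights: for internal node u, every pair of nodes
    # in different child subtrees has MRCA u
    for u in tree.postorder().tolist():
        kids = tree.children[u]
        if not kids:
            continue
        groups = [list(desc[c] | set(tree.subtree_nodes(c))) for c in kids]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi = np.fromiter(groups[i], dtype=np.int64)
                gj = np.fromiter(groups[j], dtype=np.int64)
                C[np.ix_(gi, gj)] = h[u]
                C[np.ix_(gj, gi)] = h[u]
        # the node itself vs its subtree
        sub = np.fromiter(
            (w for w in tree.subtree_nodes(u) if w != u), dtype=np.int64
        )
        C[u, sub] = h[u]
        C[sub, u] = h[u]
    return C


def bm_ancestral_latitudes(tree: Tree, tip_latitudes: dict):
    """GLS (maximum likelihood) ancestral states under single-rate BM.

    Returns ``(node_values, sigma2_hat)``: an array over all node ids
    (tips echo their data; the root gets the GLS mean) and the ML estimate
    of the BM rate in degrees^2/Myr. Non-ultrametric trees are accepted;
    near-singular covariance from zero-length branch chains gets a tiny
    ridge (logged).
    """
    y = np.empty(tree.n_tips)
    for i, lbl in enumerate(tree.tip_labels):
        if lbl not in tip_latitudes:
            raise TreeError(f"missing latitude for tip {lbl!r}")
        y[i] = float(tip_latitudes[lbl])
    C = _vcv_rows(tree)
    tips = np.arange(tree.n_tips)
    Ct = C[np.ix_(tips, tips)]
    ones = np.ones(tree.n_tips)
    try:
        Ci = np.linalg.inv(Ct)
    except np.linalg.LinAlgError:
        logger.warning("singular tip covariance; adding ridge (zero-length chain)")
        Ci = np.linalg.inv(Ct + 1e-10 * np.eye(tree.n_tips))
    mu = float(ones @ Ci @ y) / float(ones @ Ci @ ones)
    resid = y - mu
    sigma2 = float(resid @ Ci @ resid) / tree.n_tips
    values = np.empty(tree.n_nodes)
    values[tips] = y
    alpha = Ci @ resid
    for v in range(tree.n_tips, tree.n_nodes):
        cv = C[v, tips]
        values[v] = mu + float(cv @ alpha)
    values[tree.root] = mu
    return values, sigma2


def interpolate_event_latitude(parent_lat: float, child_lat: float, delta: float) -> float:
    """Linear interpolation along a branch: delta=0 at the parent node.

    latitude = delta * child + (1 - delta) * parent, so delta=0.5 is the
    branch midpoint and delta=0.1 lies 10% of the way from the parent.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must be in [0, 1]")
    return delta * child_lat + (1.0 - delta) * parent_lat


def locate_events(ensemble: MapEnsemble, node_latitudes: np.ndarray) -> pd.DataFrame:
    """Latitude and age of every change event in every map.

    Returns a table with columns map, branch (child node id), delta, type
    ('gain'/'loss'), latitude (interpolated) and age_mya (time before the
    youngest tip).
    """
    tree = ensemble.tree
    h = tree.node_heights()
    depth = tree.depth()
    rows = []
    for mi, cmap in enumerate(ensemble.maps):
        for v, evs in cmap.events.items():
            bl = float(tree.branch_length[v])
            p = tree.parent[v]
            for t, new_state in evs:
                delta = t / bl if bl > 0 else 0.0
                lat = interpolate_event_latitude(
                    float(node_latitudes[p]), float(node_latitudes[v]), delta
                )
                rows.append(
                    {
                        "map": mi,
                        "branch": int(v),
                        "delta": delta,
                        "type": "gain" if new_state == 1 else "loss",
                        "latitude": lat,
                        "age_mya": depth - (h[p] + t),
                    }
                )
    return pd.DataFrame(
        rows, columns=["map", "branch", "delta", "type", "latitude", "age_mya"]
    )


def event_latitude_density(
    events: pd.DataFrame,
    event_type: str,
    bandwidth: "float | None" = None,
    grid: "np.ndarray | None" = None,
):
    """Gaussian KDE of event latitudes for one event type.

    Bandwidth defaults to Silverman's rule (scipy's default). Returns
    ``(grid, density)``; the density integrates to 1 over the returned
    grid to within ~1e-3.
    """
    lats = events.loc[events["type"] == event_type, "latitude"].to_numpy()
    if len(lats) == 0:
        raise ValueError(f"no events of type {event_type!r}")
    if len(lats) < 2 or len(np.unique(lats)) == 1:
        # degenerate support: a narrow Gaussian around the single value
        lats = np.concatenate([lats, lats + 1e-6, lats - 1e-6])
    kde = stats.gaussian_kde(lats, bw_method=bandwidth)
    if grid is None:
        bw = np.sqrt(kde.covariance[0, 0])
        grid = np.linspace(lats.min() - 4 * bw, lats.max() + 4 * bw, 512)
    return grid, kde(grid)


def time_latitude_grid(
    events: pd.DataFrame,
    n_maps: int,
    time_edges: np.ndarray,
    lat_edges: np.ndarray,
):
    """Mean gains/losses per map in time x latitude cells, jointly scaled.

    Each cell holds (events of that type in cell) / n_maps; both grids are
    then divided by their joint maximum so gains and losses share a scale
    with maximum exactly 1 (when any event exists). Returns a dict with
    the raw and scaled grids.
    """
    out = {}
    for typ in ("gain", "loss"):
        sub = events[events["type"] == typ]
        H, _, _ = np.histogram2d(
            sub["age_mya"], sub["latitude"], bins=[time_edges, lat_edges]
        )
        out[typ] = H / n_maps
    joint_max = max(out["gain"].max(), out["loss"].max())
    scale = joint_max if joint_max > 0 else 1.0
    out["gain_scaled"] = out["gain"] / scale
    out["loss_scaled"] = out["loss"] / scale
    return out


@dataclass
class ZoneRatio:
    tropical_mean: float       # mean per-map losses in [-23, 23]
    temperate_mean: float      # mean per-map losses in (23, 35]
    ratio: float               # NaN when undefined
    defined: bool


def zone_loss_ratio(events: pd.DataFrame, n_maps: int,
                    event_type: str = "loss") -> ZoneRatio:
    """Tropical vs northern-temperate mean per-map event counts.

    Tropics are the closed band [-23, 23] degrees; the northern temperate
    zone is the half-open band (23, 35]. An empty temperate zone flags the
    ratio undefined rather than raising.
    """
    sub = events[events["type"] == event_type]
    lat = sub["latitude"].to_numpy()
    trop = float(((lat >= TROPICS[0]) & (lat <= TROPICS[1])).sum()) / n_maps
    temp = float(((lat > NORTH_TEMPERATE[0]) & (lat <= NORTH_TEMPERATE[1])).sum()) / n_maps
    if temp == 0:
        return ZoneRatio(trop, temp, float("nan"), False)
    return ZoneRatio(trop, temp, trop / temp, True)


# ----------------------------------------------------------------------
# phylogenetic independent contrasts


def _resolve_polytomies(tree: Tree) -> Tree:
    """Arbitrary binary resolution with zero-length branches (logged)."""
    if all(len(c) in (0, 2) for c in tree.children):
        return tree
    logger.info("resolving polytomies with zero-length branches")
    parent = list(tree.parent)
    children = [list(c) for c in tree.children]
    blen = list(tree.branch_length)
    labels = list(tree.labels)
    v = 0
    while v < len(children):
        while len(children[v]) > 2:
            c1 = children[v].pop()
            c2 = children[v].pop()
            new = len(parent)
            parent.append(v)
            children.append([c2, c1])
            blen.append(0.0)
            labels.append(None)
            parent[c1] = new
            parent[c2] = new
            children[v].append(new)
        v += 1
    return Tree(
        np.array(parent), children, np.array(blen), labels, tree.n_tips
    )


def phylogenetic_independent_contrasts(tree: Tree, tip_values: dict) -> np.ndarray:
    """Standardized contrasts by the standard pruning recursion.

    Polytomies are resolved arbitrarily with zero-length branches. Returns
    one contrast per internal node of the resolved tree.
    """
    tree = _resolve_polytomies(tree)
    x = np.empty(tree.n_nodes)
    vlen = np.array(tree.branch_length, dtype=float)
    for i, lbl in enumerate(tree.tip_labels):
        if lbl not in tip_values:
            raise TreeError(f"missing value for tip {lbl!r}")
        x[i] = float(tip_values[lbl])
    contrasts = []
    for v in tree.postorder().tolist():
        kids = tree.children[v]
        if not kids:
            continue
        c1, c2 = kids
        v1, v2 = vlen[c1], vlen[c2]
        denom = v1 + v2
        if denom == 0:  # zero-length pair from polytomy resolution
            contrasts.append((x[c1] - x[c2]) / math.sqrt(1e-12))
            x[v] = 0.5 * (x[c1] + x[c2])
            continue
        contrasts.append((x[c1] - x[c2]) / math.sqrt(denom))
        x[v] = (v2 * x[c1] + v1 * x[c2]) / denom
        vlen[v] = vlen[v] + v1 * v2 / denom
    return np.array(contrasts)


@dataclass
class ConservatismResult:
    observed_variance: float
    null_mean: float
    null_sd: float
    z: float
    p: float                   # one-tailed: P(null variance <= observed)
    n_perm: int
    seed: int
    degenerate: bool = False


def pic_conservatism(
    tree: Tree, tip_values: dict, n_perm: int = 1000, seed: int = 0
) -> ConservatismResult:
    """Conservatism test: contrast variance vs tip-permutation null.

    Low observed variance of the standardized contrasts relative to
    permuted tip placements means similar latitudes cluster on the tree.
    z = (observed - null mean) / null SD; one-tailed p counts null
    variances at or below the observed one.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    vals = np.array([float(tip_values[l]) for l in tree.tip_labels])
    if np.allclose(vals, vals[0]):
        raise ValueError("constant tip values: contrast variance is zero")
    contrasts = phylogenetic_independent_contrasts(tree, tip_values)
    if len(contrasts) < 2:
        return ConservatismResult(
            float("nan"), float("nan"), float("nan"), float("nan"),
            float("nan"), n_perm, seed, degenerate=True,
        )
    obs = float(np.var(contrasts, ddof=1))
    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = vals[rng.permutation(len(vals))]
        pv = dict(zip(labels, perm))
        null[b] = np.var(phylogenetic_independent_contrasts(tree, pv), ddof=1)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    degenerate = not np.isfinite(null_sd) or null_sd == 0.0
    z = float("nan") if degenerate else (obs - null_mean) / null_sd
    p = (1.0 + float((null <= obs).sum())) / (n_perm + 1.0)
    return ConservatismResult(obs, null_mean, null_sd, z, p, n_perm, seed, degenerate)
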