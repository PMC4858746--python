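"""Spatial tests of the model-mimic richness coupling.

The primary fit is a simultaneous-autoregressive (SAR) error model of
mimic richness on coral-snake (model) richness plus total richness,
y = X beta + u with u = lambda W u + eps, estimated by maximum likelihood
with the log-determinant evaluated from the eigenvalues of the neighbor
weight matrix W. Neighborhoods are great-circle distance bands grown in
50-km steps from the smallest feasible size; binary, distance and
inverse-distance weightings are compared by AIC. A label-randomization
permutation test provides a null that preserves every range polygon, the
per-cell richness totals and the coral-snake raster exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "NeighborWeights",
    "SARFit",
    "PermutationResult",
    "haversine_km",
    "build_neighbor_weights",
    "min_feasible_threshold",
    "fit_sar_error",
    "select_neighborhood",
    "morans_i",
    "permutation_test",
    "residual_z",
    "InfeasibleThresholdError",
]

EARTH_RADIUS_KM = 6371.0


class InfeasibleThresholdError(ValueError):
    pass


def haversine_km(coords_a: np.ndarray, coords_b: "np.ndarray | None" = None) -> np.ndarray:
    """Great-circle distance matrix (km) between (lon, lat) degree arrays."""
    a = np.radians(np.atleast_2d(coords_a))
    b = a if coords_b is None else np.radians(np.atleast_2d(coords_b))
    lon1, lat1 = a[:, 0][:, None], a[:, 1][:, None]
    lon2, lat2 = b[:, 0][None, :], b[:, 1][None, :]
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclass
class NeighborWeights:
    """Row-standardized spatial weights over cell midpoints."""

    coords: np.ndarray          # (n, 2) lon/lat midpoints
    W: np.ndarray               # (n, n) row-standardized weights
    base: np.ndarray            # pre-standardization symmetric weights
    threshold_km: float
    style: str                  # binary | distance | inverse-distance
    _eigs: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.coords)

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W (row-standardized symmetric base)."""
        if self._eigs is None:
            # W = D^-1 S with S symmetric is similar to D^-1/2 S D^-1/2
            d = self.base.sum(axis=1)
            sym = self.base / np.sqrt(np.outer(d, d))
            self._eigs = np.linalg.eigvalsh(sym)
        return self._eigs


def min_feasible_threshold(coords: np.ndarray, step_km: float = 50.0) -> float:
    """Smallest multiple of ``step_km`` giving every cell a neighbor."""
    d = haversine_km(coords)
    np.fill_diagonal(d, np.inf)
    floor = float(d.min(axis=1).max())
    return math.ceil(floor / step_km) * step_km


def build_neighbor_weights(
    coords: np.ndarray, threshold_km: float, style: str = "binary"
) -> NeighborWeights:
    """Distance-band weights: pairs within ``threshold_km`` are neighbors.

    Styles: 'binary' (w=1), 'distance' (w=d_ij) and 'inverse-distance'
    (w=1/d_ij). Rows are standardized to sum to one. Raises
    :class:`InfeasibleThresholdError` naming the first isolated cell.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least two cells")
    d = haversine_km(coords)
    np.fill_diagonal(d, np.inf)
    adj = d <= threshold_km
    isolated = np.where(~adj.any(axis=1))[0]
    if len(isolated):
        raise InfeasibleThresholdError(
            f"cell {isolated[0]} has no neighbor within {threshold_km} km"
        )
    if style == "binary":
        base = adj.astype(float)
    elif style == "distance":
        base = np.where(adj, d, 0.0)
    elif style == "inverse-distance":
        with np.errstate(divide="ignore"):
            base = np.where(adj, 1.0 / d, 0.0)
    else:
        raise ValueError(f"unknown weight style {style!r}")
    W = base / base.sum(axis=1, keepdims=True)
    return NeighborWeights(coords, W, base, float(threshold_km), style)


@dataclass
class SARFit:
    params: np.ndarray          # beta (intercept first)
    param_names: list
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    lam: float                  # error-autoregression lambda
    lam_se: float
    sigma2: float
    loglik: float
    aic: float
    residuals: np.ndarray       # u = y - X beta
    weights: NeighborWeights
    morans_i_residuals: float = np.nan
    _profile: "object" = None   # concentrated -lnL(lambda), for LR intervals
    _lam_bounds: tuple = (None, None)

    def lam_confint(self, level: float = 0.95) -> tuple:
        """Profile-likelihood interval for lambda (LR inversion).

        Better-calibrated than the Wald interval when lambda sits near
        the edge of its stable range.
        """
        from scipy.optimize import brentq
        from scipy.stats import chi2

        if self._profile is None:
            raise RuntimeError("profile function unavailable")
        cut = chi2.ppf(level, df=1) / 2.0
        nll_hat = self._profile(self.lam)

        def g(l):
            return (self._profile(l) - nll_hat) - cut

        lo_b, hi_b = self._lam_bounds
        eps = 1e-8
        lo = lo_b + eps if g(lo_b + eps) <= 0 else brentq(g, lo_b + eps, self.lam)
        hi = hi_b - eps if g(hi_b - eps) <= 0 else brentq(g, self.lam, hi_b - eps)
        return float(lo), float(hi)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "z": self.zvalues,
             "p": self.pvalues},
            index=self.param_names,
        )


def _add_intercept(X: np.ndarray, names: "list | None"):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < X.shape[1]:
        X = X.T
    if names is None:
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    return np.column_stack([np.ones(len(X)), X]), ["intercept"] + list(names)


def fit_sar_error(
    y: np.ndarray,
    X: np.ndarray,
    weights: NeighborWeights,
    names: "list | None" = None,
) -> SARFit:
    """ML fit of the SAR error model y = X beta + u, u = lambda W u + eps.

    The likelihood is concentrated: for each lambda, beta and sigma^2 come
    from OLS on the spatially filtered variables (I - lambda W)y and
    (I - lambda W)X, and ln|I - lambda W| is evaluated from the
    eigenvalues of W. An intercept is prepended automatically.
    """
    y = np.asarray(y, dtype=float).ravel()
    Xf, names = _add_intercept(X, names)
    n, p = Xf.shape
    if n != len(y) or n != weights.n:
        raise ValueError("y, X and W dimensions disagree")
    if np.linalg.matrix_rank(Xf) < p:
        raise ValueError("collinear predictors")
    W = weights.W
    eigs = weights.eigenvalues()
    lam_lo = 1.0 / eigs.min() + 1e-6 if eigs.min() < 0 else -0.9999
    lam_hi = 1.0 / eigs.max() - 1e-6

    def profile(lam):
        A = np.eye(n) - lam * W
        ys, Xs = A @ y, A @ Xf
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        resid = ys - Xs @ beta
        sigma2 = float(resid @ resid) / n
        if sigma2 <= 0:
            return np.inf, beta, sigma2
        logdet = float(np.sum(np.log(1.0 - lam * eigs)))
        ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet
        return -ll, beta, sigma2

    res = minimize_scalar(
        lambda l: profile(l)[0], bounds=(lam_lo, lam_hi), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(res.x)
    nll, beta, sigma2 = profile(lam)
    if not np.isfinite(nll):
        raise RuntimeError(f"SAR optimization failed: {res}")
    loglik = -nll
    A = np.eye(n) - lam * W
    Xs = A @ Xf
    cov_beta = sigma2 * np.linalg.inv(Xs.T @ Xs)
    bse = np.sqrt(np.diag(cov_beta))
    zvals = beta / bse
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    # lambda SE from the curvature of the profile log-likelihood
    h = max(1e-5, 1e-4 * (lam_hi - lam_lo))
    if lam - h > lam_lo and lam + h < lam_hi:
        d2 = (profile(lam + h)[0] - 2 * nll + profile(lam - h)[0]) / h**2
        lam_se = float(1.0 / math.sqrt(d2)) if d2 > 0 else np.nan
    else:
        lam_se = np.nan
    k = p + 2  # betas + lambda + sigma^2
    fit = SARFit(
        params=beta, param_names=names, bse=bse, zvalues=zvals, pvalues=pvals,
        lam=lam, lam_se=lam_se, sigma2=sigma2, loglik=loglik,
        aic=2 * k - 2 * loglik, residuals=y - Xf @ beta, weights=weights,
        _profile=lambda l: profile(l)[0], _lam_bounds=(lam_lo, lam_hi),
    )
    fit.morans_i_residuals = morans_i(fit.residuals, weights, n_perm=0)[0]
    return fit


def select_neighborhood(
    y: np.ndarray,
    X: np.ndarray,
    coords: np.ndarray,
    step_km: float = 50.0,
    max_steps: int = 10,
    styles: tuple = ("binary", "distance", "inverse-distance"),
    names: "list | None" = None,
):
    """AIC grid search over neighborhood sizes and weighting styles.

    Thresholds run from the smallest feasible size upward in ``step_km``
    increments (``max_steps`` candidates); failed fits are recorded and
    skipped. Returns ``(best_fit, aic_table)``.
    """
    coords = np.asarray(coords, dtype=float)
    t0 = min_feasible_threshold(coords, step_km)
    rows, best = [], None
    for i in range(max_steps):
        thr = t0 + i * step_km
        for style in styles:
            try:
                w = build_neighbor_weights(coords, thr, style)
                fit = fit_sar_error(y, X, w, names=names)
                rows.append(
                    {"threshold_km": thr, "style": style, "aic": fit.aic,
                     "loglik": fit.loglik, "lambda": fit.lam, "error": None}
                )
                if best is None or fit.aic < best.aic:
                    best = fit
            except Exception as exc:
                rows.append(
                    {"threshold_km": thr, "style": style, "aic": np.nan,
                     "loglik": np.nan, "lambda": np.nan, "error": str(exc)}
                )
    if best is None:
        raise RuntimeError("no SAR candidate could be fit")
    return best, pd.DataFrame(rows)


def morans_i(
    x: np.ndarray,
    weights: NeighborWeights,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
):
    """Global Moran's I with a permutation p-value.

    I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2) with z the
    centered variable. ``n_perm=0`` skips the test (p is NaN).
    """
    x = np.asarray(x, dtype=float).ravel()
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("Moran's I undefined for a constant variable")
    W = weights.W
    n = len(x)
    s0 = float(W.sum())

    def stat(zv):
        return (n / s0) * float(zv @ W @ zv) / float(zv @ zv)

    i_obs = stat(z)
    if n_perm <= 0:
        return i_obs, float("nan")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        zp = z[rng.permutation(n)]
        null[b] = stat(zp)
    e_i = -1.0 / (n - 1)
    if alternative == "greater":
        extreme = null >= i_obs
    elif alternative == "less":
        extreme = null <= i_obs
    else:
        extreme = np.abs(null - e_i) >= abs(i_obs - e_i)
    p = (1.0 + int(extreme.sum())) / (n_perm + 1.0)
    return i_obs, p


@dataclass
class PermutationResult:
    observed_slope: float
    null_slopes: np.ndarray
    p: float                    # (# null >= observed) / n_iter, as printed
    p_conservative: float       # (b + 1) / (n + 1) lower-bound convention
    null_mean_mimic: np.ndarray  # per-cell mean mimic richness under the null
    seed: int


def _ols_model_slope(mimic_counts, model_counts, total_counts):
    Xf = np.column_stack(
        [np.ones(len(model_counts)), model_counts, total_counts]
    )
    beta, *_ = np.linalg.lstsq(Xf, mimic_counts, rcond=None)
    return float(beta[1])


def permutation_test(
    presence: dict,
    tags: dict,
    onland: np.ndarray,
    n_iter: int = 1000,
    seed: int = 0,
    cell_mask: "np.ndarray | None" = None,
) -> PermutationResult:
    """Label-randomization null for the model-mimic richness coupling.

    Species identity tags of all non-model (non-coral-snake) range
    polygons are shuffled without replacement before richness rasters are
    rebuilt, so every null iteration preserves (a) the range geometries,
    (b) the per-cell total richness and (c) the model raster exactly.
    Each iteration records the OLS slope of mimic richness on model
    richness + total richness; the one-tailed p is the fraction of null
    slopes at or above the observed slope.

    ``presence`` maps species -> boolean presence grid; ``tags`` maps
    species -> {'model', 'mimic', 'other'}.
    """
    species = sorted(presence)
    tag_arr = np.array([tags[sp] for sp in species])
    if (tag_arr == "mimic").sum() == 0 or (tag_arr == "model").sum() == 0:
        raise ValueError("need at least one mimic and one model species")
    mask = onland if cell_mask is None else (onland & cell_mask)
    cols = np.stack([presence[sp][mask] for sp in species])  # (n_sp, n_cells)
    model_counts = cols[tag_arr == "model"].sum(axis=0)
    total_counts = cols.sum(axis=0)
    mimic_counts = cols[tag_arr == "mimic"].sum(axis=0)
    obs = _ols_model_slope(mimic_counts, model_counts, total_counts)

    non_model = np.where(tag_arr != "model")[0]
    labels = tag_arr[non_model]
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    null_mean = np.zeros(mask.sum())
    for b in range(n_iter):
        shuffled = labels[rng.permutation(len(labels))]
        mim = cols[non_model[shuffled == "mimic"]].sum(axis=0)
        null[b] = _ols_model_slope(mim, model_counts, total_counts)
        null_mean += mim
    null_mean /= n_iter
    p = float((null >= obs).sum()) / n_iter
    p_cons = (float((null >= obs).sum()) + 1.0) / (n_iter + 1.0)
    full = np.full(mask.shape, np.nan)
    full[mask] = null_mean
    return PermutationResult(obs, null, p, p_cons, full, seed)


def residual_z(f, fbar, null_sd=None):
    """Standardized residual z = (f - fbar) / sqrt(fbar).

    The chi-square-framework residual for the per-cell mimic count against
    its permutation-null mean; cells with fbar = 0 are masked (NaN).
    Passing ``null_sd`` switches the denominator to the null standard
    deviation instead.
    """
    f = np.asarray(f, dtype=float)
    fbar = np.asarray(fbar, dtype=float)
    if np.any(f < 0) or np.any(fbar < 0):
        raise ValueError("counts must be non-negative")
    denom = np.sqrt(fbar) if null_sd is None else np.asarray(null_sd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, (f - fbar) / np.where(denom > 0, denom, 1.0), np.nan)
    return z
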