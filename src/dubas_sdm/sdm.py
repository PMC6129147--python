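"""The three suitability learners and the sampling-bias machinery.

Learners
--------
* :class:`MaxEntModel` — maximum-entropy density estimation: a Gibbs
  distribution over background cells whose feature expectations are pulled
  (within an L1 budget ``beta``) toward the presence feature means; fitted by
  proximal gradient on the penalized log-likelihood.
* :class:`StepwiseLogistic` — binomial GLM fitted by iteratively reweighted
  least squares, with bidirectional stepwise term selection by AIC over
  linear and quadratic terms.
* :class:`BoostedTrees` — stagewise gradient boosting on binomial deviance;
  each shallow regression tree is fitted to the current negative gradient by
  greedy variance-reduction splits, with Newton leaf values.

Bias machinery
--------------
Survey effort is estimated as a Gaussian kernel density of the records; the
background sample is drawn proportionally to that density (bias matching)
and presence records are weighted by the inverse relative density, linearly
rescaled to the interval [1, 20] so oversampled localities are down-weighted
without extreme values.

All features are standardized against the background mean/sd; projection
onto new climate never clamps features to the training range.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._base import BaseEstimator, check_is_fitted
from .errors import FitError
from .geodata import ClimateStack, OccurrenceTable, RasterGrid, extract_at

logger = logging.getLogger(__name__)

WEIGHT_MIN, WEIGHT_MAX = 1.0, 20.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# Survey-effort weighting and background sampling
# ---------------------------------------------------------------------------

def default_kernel_sd(geometry: RasterGrid) -> float:
    """Kernel bandwidth rule: shorter extent side divided by 30 (degrees)."""
    width = geometry.n_cols * geometry.cell_size
    height = geometry.n_rows * geometry.cell_size
    return min(width, height) / 30.0


def record_density(occ: OccurrenceTable, geometry: RasterGrid, sd: float | None = None) -> RasterGrid:
    """Gaussian kernel density of records per cell.

    The smoothed record count in each cell is divided by the smoothed count
    of valid (unmasked) cells, which removes the edge/coastline falloff of a
    plain kernel sum: a perfectly uniform record layout yields a constant
    density.
    """
    if sd is None:
        sd = default_kernel_sd(geometry)
    if not sd > 0:
        raise ValueError("kernel sd must be positive")
    counts = np.zeros(geometry.shape)
    row, col, inside = geometry.index_of(occ.lon, occ.lat)
    np.add.at(counts, (row[inside], col[inside]), 1.0)
    counts[geometry.nodata_mask] = 0.0
    sigma = sd / geometry.cell_size
    smoothed = gaussian_filter(counts, sigma=sigma, mode="constant")
    support = gaussian_filter((~geometry.nodata_mask).astype(float), sigma=sigma,
                              mode="constant")
    dens = np.divide(smoothed, support, out=np.zeros_like(smoothed),
                     where=support > 0)
    dens[geometry.nodata_mask] = np.nan
    return geometry.copy_with(dens)


def kernel_weight_surface(
    occ: OccurrenceTable, geometry: RasterGrid, sd: float | None = None
) -> RasterGrid:
    """Record-importance surface in [1, 20].

    Inverse relative kernel density, linearly rescaled so the least-sampled
    cell maps to 20 and the densest to 1 ("greater importance to records with
    less geographic proximity"). Densities are floored at 1% of the mean
    unmasked density before inversion so empty corners do not dominate the
    rescaling. A constant density maps everywhere to 1.
    """
    if len(occ) < 1:
        raise ValueError("need at least one record")
    dens = record_density(occ, geometry, sd)
    v = dens.values.copy()
    unmasked = ~dens.nodata_mask
    floor = max(v[unmasked].mean() * 0.01, 1e-300)
    inv = 1.0 / np.maximum(v, floor)
    lo, hi = inv[unmasked].min(), inv[unmasked].max()
    if hi - lo < 1e-12 * max(hi, 1.0):
        w = np.full(geometry.shape, WEIGHT_MIN)
    else:
        w = WEIGHT_MIN + (WEIGHT_MAX - WEIGHT_MIN) * (inv - lo) / (hi - lo)
    w[dens.nodata_mask] = np.nan
    return dens.copy_with(w)


def record_weights(surface: RasterGrid, occ: OccurrenceTable) -> np.ndarray:
    """Per-record weights read off the weight surface (1 outside the grid)."""
    row, col, inside = surface.index_of(occ.lon, occ.lat)
    w = np.ones(len(occ))
    r, c = row[inside], col[inside]
    vals = surface.values[r, c]
    w[inside] = np.where(np.isfinite(vals), vals, 1.0)
    return np.clip(w, WEIGHT_MIN, WEIGHT_MAX)


def sample_background(
    density: RasterGrid, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw n background (lon, lat) points with cell probability ∝ density."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.where(density.nodata_mask, 0.0, np.nan_to_num(density.values))
    p = np.maximum(p, 0.0).ravel()
    if p.sum() <= 0:
        logger.warning("sample_background: all-zero density; falling back to uniform")
        p = (~density.nodata_mask).ravel().astype(float)
    idx = rng.choice(p.size, size=n, replace=True, p=p / p.sum())
    rows, cols = np.unravel_index(idx, density.shape)
    cs = density.cell_size
    lon = density.x_origin + (cols + 0.5) * cs
    lat = density.y_origin + (density.n_rows - rows - 0.5) * cs
    return np.column_stack([lon, lat])


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Standardized presence/background features with sample weights."""

    X: np.ndarray                # (n, n_terms)
    term_names: list[str]        # e.g. ["bio2", "bio5", "bio2^2", ...]
    labels: np.ndarray           # 1 presence, 0 background
    weights: np.ndarray
    layer_names: list[str]
    bg_mean: np.ndarray          # per layer
    bg_sd: np.ndarray
    quadratic: bool

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels).astype(int)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.X).all():
            raise ValueError("feature table contains missing values")
        if (self.weights <= 0).any():
            raise ValueError("sample weights must be positive")

    @property
    def presence(self) -> np.ndarray:
        return self.labels == 1

    def featurize(self, raw: np.ndarray) -> np.ndarray:
        """Standardize raw layer values (n, n_layers) into model terms (no clamping)."""
        z = (np.asarray(raw, dtype=float) - self.bg_mean) / self.bg_sd
        return np.column_stack([z, z**2]) if self.quadratic else z


def build_feature_table(
    stack: ClimateStack,
    presence_points,
    background_points,
    presence_weights=None,
    quadratic: bool = True,
) -> FeatureTable:
    """Extract, standardize (against background) and expand features."""
    names = stack.names
    pres = np.atleast_2d(np.asarray(presence_points, dtype=float))
    bg = np.atleast_2d(np.asarray(background_points, dtype=float))
    dfp = extract_at(stack, pres)
    dfb = extract_at(stack, bg)
    okp = (dfp["in_bounds"] & ~dfp["masked"]).to_numpy()
    okb = (dfb["in_bounds"] & ~dfb["masked"]).to_numpy()
    if okp.sum() < len(pres) or okb.sum() < len(bg):
        logger.warning("build_feature_table: dropped %d presence / %d background points off-grid or masked",
                       len(pres) - okp.sum(), len(bg) - okb.sum())
    vp = dfp.loc[okp, names].to_numpy(float)
    vb = dfb.loc[okb, names].to_numpy(float)
    if len(vp) < 1 or len(vb) < 2:
        raise FitError("need at least 1 valid presence and 2 background points")
    mean = vb.mean(axis=0)
    sd = vb.std(axis=0)
    sd[sd == 0] = 1.0
    wp = np.ones(len(vp)) if presence_weights is None else np.asarray(presence_weights, float)[okp]
    ft = FeatureTable(
        X=np.empty((0, 0)), term_names=[], labels=np.empty(0, int), weights=np.empty(0),
        layer_names=list(names), bg_mean=mean, bg_sd=sd, quadratic=quadratic,
    )
    raw = np.vstack([vp, vb])
    ft.X = ft.featurize(raw)
    ft.term_names = list(names) + ([f"{n}^2" for n in names] if quadratic else [])
    ft.labels = np.concatenate([np.ones(len(vp), int), np.zeros(len(vb), int)])
    ft.weights = np.concatenate([wp, np.ones(len(vb))])
    return ft


# ---------------------------------------------------------------------------
# MaxEnt
# ---------------------------------------------------------------------------

#: Coefficient cap applied when the MaxEnt optimum is unbounded (beta = 0
#: with separable presence/background features).
MAXENT_LAMBDA_CAP = 30.0


class MaxEntModel(BaseEstimator):
    """L1-regularized maximum-entropy (Gibbs) density over background cells.

    Maximizes ``mean_w[presence score] - log sum_bg exp(score) - beta*||lambda||_1``
    by proximal gradient (ISTA with backtracking line search). At convergence
    each feature satisfies ``|E_model[f] - weighted presence mean[f]| <= beta``
    up to tolerance (KKT condition of the L1 problem).

    The [0,1] output is a logistic transform of the linear score centred so
    that the weighted mean presence score maps to 0.5; the raw normalized
    density over the background is exposed via :meth:`predict_raw`.
    """

    def __init__(self, beta: float = 0.05, max_iter: int = 3000, tol: float = 1e-6):
        self.beta = beta
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, features: FeatureTable) -> "MaxEntModel":
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        pres = features.presence
        if pres.sum() < 1 or (~pres).sum() < 2:
            raise FitError("MaxEnt needs >= 1 presence and >= 2 background rows")
        Fp = features.X[pres]
        wp = features.weights[pres]
        Fb = features.X[~pres]
        wb = features.weights[~pres]
        log_wb = np.log(wb)
        fbar = np.average(Fp, axis=0, weights=wp)

        n_feat = features.X.shape[1]
        lam = np.zeros(n_feat)

        def logZ_and_expect(l):
            # background weights act as the base measure of the Gibbs density
            eta = Fb @ l + log_wb
            m = eta.max()
            e = np.exp(eta - m)
            Z = e.sum()
            return m + np.log(Z), (Fb * e[:, None]).sum(axis=0) / Z

        def smooth_neg(l):
            lz, _ = logZ_and_expect(l)
            return lz - l @ fbar

        # FISTA (accelerated proximal gradient) with backtracking and restart
        step = 1.0
        z = lam.copy()
        t = 1.0
        f_lam = smooth_neg(lam)
        converged = False
        it = 0
        for it in range(self.max_iter):
            f_z = smooth_neg(z)
            _, expect = logZ_and_expect(z)
            grad = expect - fbar
            while True:
                cand = z - step * grad
                cand = np.sign(cand) * np.maximum(np.abs(cand) - step * self.beta, 0.0)
                # cap coefficients: with beta = 0 and separable data the
                # optimum is at infinity (cf. GLM separation handling)
                cand = np.clip(cand, -MAXENT_LAMBDA_CAP, MAXENT_LAMBDA_CAP)
                f_new = smooth_neg(cand)
                diff = cand - z
                quad = f_z + grad @ diff + (diff @ diff) / (2 * step)
                if (np.isfinite(f_new) and f_new <= quad + 1e-12) or step < 1e-14:
                    break
                step *= 0.5
            if f_new + self.beta * np.abs(cand).sum() > f_lam + self.beta * np.abs(lam).sum():
                # restart momentum when the objective would increase
                z = lam.copy()
                t = 1.0
                continue
            t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
            z = cand + ((t - 1.0) / t_new) * (cand - lam)
            moved = np.max(np.abs(cand - lam))
            lam, f_lam, t = cand, f_new, t_new
            step *= 1.2
            if moved < self.tol * max(1.0, np.max(np.abs(lam))):
                converged = True
                break
        if not converged:
            logger.warning("MaxEnt did not converge in %d iterations", self.max_iter)

        self.lambda_ = lam
        self.converged_ = converged
        self.n_iter_ = it + 1
        eta_b = Fb @ lam + log_wb
        m = eta_b.max()
        self.log_z_ = m + np.log(np.exp(eta_b - m).sum())
        self.center_ = float(np.average(Fp @ lam, axis=0, weights=wp))
        self.presence_mean_ = fbar
        self.background_expectation_ = logZ_and_expect(lam)[1]
        self.fitted_background_p_ = np.exp(eta_b - self.log_z_)
        self.background_log_weight_offset_ = float(np.log(wb.mean()))
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "lambda_")
        return np.asarray(X, dtype=float) @ self.lambda_

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Unnormalized Gibbs density exp(score - logZ) (sums to 1 on the
        training background)."""
        return np.exp(self.decision_function(X) - self.log_z_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Logistic-style output in [0, 1]; 0.5 at the mean presence score."""
        return _sigmoid(self.decision_function(X) - self.center_)


# ---------------------------------------------------------------------------
# GLM: IRLS + stepwise AIC
# ---------------------------------------------------------------------------

#: Coefficient cap applied under (quasi-)complete separation.
GLM_BETA_CAP = 15.0


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, w: np.ndarray,
    max_iter: int = 100, tol: float = 1e-10, cap: float = GLM_BETA_CAP,
) -> tuple[np.ndarray, float, bool]:
    """Weighted binomial IRLS on a design that already includes the intercept.

    Returns (beta, weighted log-likelihood, converged). Coefficients are
    capped at +-cap; hitting the cap flags non-convergence (separation).
    """
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = _sigmoid(eta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        W = w * p * (1 - p)
        z = eta + (y - p) / (p * (1 - p))
        WX = X * W[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(X * np.sqrt(W)[:, None], z * np.sqrt(W), rcond=None)[0]
        capped = np.abs(beta_new) > cap
        if capped.any():
            beta_new = np.clip(beta_new, -cap, cap)
        p_new = np.clip(_sigmoid(X @ beta_new), 1e-12, 1 - 1e-12)
        ll = float(np.sum(w * (y * np.log(p_new) + (1 - y) * np.log(1 - p_new))))
        if ll < ll_old - 1e-9:            # step-halving on deviance increase
            beta_new = (beta + beta_new) / 2
            p_new = np.clip(_sigmoid(X @ beta_new), 1e-12, 1 - 1e-12)
            ll = float(np.sum(w * (y * np.log(p_new) + (1 - y) * np.log(1 - p_new))))
        if np.max(np.abs(beta_new - beta)) < tol and not capped.any():
            beta = beta_new
            ll_old = ll
            converged = True
            break
        beta = beta_new
        ll_old = ll
    if not converged and np.abs(beta).max() >= cap - 1e-9:
        logger.warning("IRLS: separation suspected; coefficients capped at +-%g", cap)
    return beta, ll_old, converged


class StepwiseLogistic(BaseEstimator):
    """Binomial GLM with bidirectional stepwise AIC term selection.

    Starting from the intercept-only model, each step tries adding any
    excluded term and dropping any included one, taking the move with the
    best AIC improvement; AIC = -2*loglik + 2*(terms + 1). The final model's
    AIC is never above the intercept-only model's.
    """

    def __init__(self, max_steps: int = 100, max_iter: int = 100, tol: float = 1e-10):
        self.max_steps = max_steps
        self.max_iter = max_iter
        self.tol = tol

    def _fit_terms(self, F: FeatureTable, terms: tuple[int, ...]):
        X = np.column_stack([np.ones(len(F.labels))] + [F.X[:, j] for j in terms])
        beta, ll, conv = _irls_logistic(
            X, F.labels.astype(float), F.weights, self.max_iter, self.tol
        )
        aic = -2 * ll + 2 * (len(terms) + 1)
        return beta, ll, aic, conv

    def fit(self, features: FeatureTable) -> "StepwiseLogistic":
        n_terms = features.X.shape[1]
        if len(features.labels) <= n_terms + 1:
            raise FitError("need n > number of candidate terms")
        cache: dict[tuple[int, ...], tuple] = {}

        def fit_cached(terms: tuple[int, ...]):
            if terms not in cache:
                cache[terms] = self._fit_terms(features, terms)
            return cache[terms]

        current: tuple[int, ...] = ()
        _, _, best_aic, _ = fit_cached(current)
        for _ in range(self.max_steps):
            candidates: list[tuple[float, tuple[int, ...]]] = []
            for j in range(n_terms):
                if j not in current:
                    t = tuple(sorted(current + (j,)))
                    candidates.append((fit_cached(t)[2], t))
            for j in current:
                t = tuple(k for k in current if k != j)
                candidates.append((fit_cached(t)[2], t))
            if not candidates:
                break
            cand_aic, cand_terms = min(candidates, key=lambda c: (c[0], c[1]))
            if cand_aic < best_aic - 1e-9:
                best_aic, current = cand_aic, cand_terms
            else:
                break
        beta, ll, aic, conv = fit_cached(current)
        self.terms_ = current
        self.term_names_ = [features.term_names[j] for j in current]
        self.coef_ = beta
        self.loglik_ = ll
        self.aic_ = aic
        self.converged_ = conv
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        Xd = np.column_stack([np.ones(len(X))] + [X[:, j] for j in self.terms_])
        return Xd @ self.coef_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision_function(X))


# ---------------------------------------------------------------------------
# BRT
# ---------------------------------------------------------------------------

#: Newton leaf values are capped at this magnitude for stability.
BRT_LEAF_CAP = 4.0


def _build_tree(X, grad, hess, w, idx, depth, min_leaf):
    """Greedy variance-reduction regression tree on the negative gradient.

    Returns nested dicts: {"feature", "threshold", "left", "right"} or
    {"value"} at leaves; leaf value is the (capped) Newton step
    sum(w*grad)/sum(w*hess).
    """
    def leaf(ids):
        denom = np.sum(w[ids] * hess[ids])
        num = np.sum(w[ids] * grad[ids])
        v = num / denom if denom > 1e-12 else 0.0
        return {"value": float(np.clip(v, -BRT_LEAF_CAP, BRT_LEAF_CAP))}

    if depth == 0 or np.sum(w[idx]) < 2 * min_leaf:
        return leaf(idx)
    r, ww = grad[idx], w[idx]
    best = None   # (gain, feature, threshold, order, split_pos)
    base_num = np.sum(ww * r)
    base_den = np.sum(ww)
    base_score = base_num**2 / base_den if base_den > 0 else 0.0
    for f in range(X.shape[1]):
        xv = X[idx, f]
        order = np.argsort(xv, kind="stable")
        xs, rs, ws = xv[order], r[order], ww[order]
        cw = np.cumsum(ws)
        cr = np.cumsum(ws * rs)
        distinct = xs[:-1] < xs[1:]
        pos = np.flatnonzero(distinct)
        # min_leaf counts weighted mass so duplicated rows and doubled
        # weights behave identically
        pos = pos[(cw[pos] >= min_leaf) & (base_den - cw[pos] >= min_leaf)]
        if len(pos) == 0:
            continue
        lw, lr = cw[pos], cr[pos]
        rw, rr = base_den - lw, base_num - lr
        gain = lr**2 / lw + rr**2 / rw - base_score
        j = int(np.argmax(gain))
        if best is None or gain[j] > best[0] + 1e-15:
            thr = 0.5 * (xs[pos[j]] + xs[pos[j] + 1])
            best = (float(gain[j]), f, thr, order, pos[j])
    if best is None or best[0] <= 1e-12:
        return leaf(idx)
    _, f, thr, order, _ = best
    left_mask = X[idx, f] <= thr
    return {
        "feature": int(f),
        "threshold": float(thr),
        "left": _build_tree(X, grad, hess, w, idx[left_mask], depth - 1, min_leaf),
        "right": _build_tree(X, grad, hess, w, idx[~left_mask], depth - 1, min_leaf),
    }


def _predict_tree(node, X, out, idx):
    if "value" in node:
        out[idx] = node["value"]
        return
    left = X[idx, node["feature"]] <= node["threshold"]
    _predict_tree(node["left"], X, out, idx[left])
    _predict_tree(node["right"], X, out, idx[~left])


class BoostedTrees(BaseEstimator):
    """Stagewise gradient boosting on binomial deviance.

    Each stage fits a depth-limited regression tree to the negative gradient
    (y - p) on a bagged subsample, with Newton leaf updates; the defaults
    follow common ecological practice (slow learning rate, shallow trees,
    0.75 bagging).
    """

    def __init__(
        self,
        n_trees: int = 150,
        learning_rate: float = 0.05,
        tree_depth: int = 3,
        bag_fraction: float = 0.75,
        min_leaf: int = 3,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.learning_rate = learning_rate
        self.tree_depth = tree_depth
        self.bag_fraction = bag_fraction
        self.min_leaf = min_leaf
        self.random_state = random_state

    def fit(self, features: FeatureTable) -> "BoostedTrees":
        if self.n_trees < 1 or self.tree_depth < 1:
            raise ValueError("n_trees and tree_depth must be >= 1")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must be in (0, 1]")
        X = features.X
        y = features.labels.astype(float)
        w = features.weights
        rng = np.random.default_rng(self.random_state)
        pbar = np.clip(np.average(y, weights=w), 1e-12, 1 - 1e-12)
        self.base_score_ = float(np.log(pbar / (1 - pbar)))
        score = np.full(len(y), self.base_score_)
        self.trees_ = []
        self.train_deviance_ = []
        n = len(y)
        n_bag = max(int(round(self.bag_fraction * n)), 2 * self.min_leaf)
        for _ in range(self.n_trees):
            p = _sigmoid(score)
            grad = y - p
            hess = np.maximum(p * (1 - p), 1e-12)
            if self.bag_fraction < 1:
                bag = rng.choice(n, size=min(n_bag, n), replace=False)
            else:
                bag = np.arange(n)
            tree = _build_tree(X, grad, hess, w, bag, self.tree_depth, self.min_leaf)
            self.trees_.append(tree)
            upd = np.empty(n)
            _predict_tree(tree, X, upd, np.arange(n))
            score = score + self.learning_rate * upd
            p = np.clip(_sigmoid(score), 1e-12, 1 - 1e-12)
            dev = -2 * np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p)))
            self.train_deviance_.append(float(dev))
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=float)
        score = np.full(len(X), self.base_score_)
        upd = np.empty(len(X))
        for tree in self.trees_:
            _predict_tree(tree, X, upd, np.arange(len(X)))
            score += self.learning_rate * upd
        return score

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision_function(X))


# ---------------------------------------------------------------------------
# Fit container and raster prediction
# ---------------------------------------------------------------------------

@dataclass
class SdmFit:
    """A fitted suitability model plus the feature recipe to apply it anywhere."""

    kind: str                      # maxent | glm | brt
    model: object
    layer_names: list[str]
    term_names: list[str]
    bg_mean: np.ndarray
    bg_sd: np.ndarray
    quadratic: bool
    metadata: dict = field(default_factory=dict)

    def featurize(self, raw: np.ndarray) -> np.ndarray:
        z = (np.asarray(raw, dtype=float) - self.bg_mean) / self.bg_sd
        return np.column_stack([z, z**2]) if self.quadratic else z

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def fit_maxent(features: FeatureTable, beta: float = 0.05,
               max_iter: int = 3000, tol: float = 1e-6) -> SdmFit:
    model = MaxEntModel(beta=beta, max_iter=max_iter, tol=tol).fit(features)
    return _wrap("maxent", model, features,
                 {"iterations": model.n_iter_, "converged": model.converged_})


def fit_glm_stepwise(features: FeatureTable, max_steps: int = 100) -> SdmFit:
    model = StepwiseLogistic(max_steps=max_steps).fit(features)
    return _wrap("glm", model, features,
                 {"aic": model.aic_, "terms": model.term_names_,
                  "converged": model.converged_})


def fit_brt(features: FeatureTable, n_trees: int = 150, learning_rate: float = 0.05,
            tree_depth: int = 3, bag_fraction: float = 0.75, seed: int = 0) -> SdmFit:
    model = BoostedTrees(
        n_trees=n_trees, learning_rate=learning_rate, tree_depth=tree_depth,
        bag_fraction=bag_fraction, random_state=seed,
    ).fit(features)
    return _wrap("brt", model, features, {"n_trees": n_trees})


def _wrap(kind: str, model, features: FeatureTable, metadata: dict) -> SdmFit:
    return SdmFit(
        kind=kind, model=model,
        layer_names=list(features.layer_names),
        term_names=list(features.term_names),
        bg_mean=features.bg_mean.copy(), bg_sd=features.bg_sd.copy(),
        quadratic=features.quadratic, metadata=metadata,
    )


def predict_sdm(fit: SdmFit, stack: ClimateStack) -> RasterGrid:
    """Apply a fitted model to a climate stack; scores in [0,1], no clamping."""
    missing = [n for n in fit.layer_names if n not in stack.names]
    if missing:
        raise KeyError(f"stack is missing layers required by the fit: {missing}")
    geom = stack.geometry
    unmasked = ~geom.nodata_mask
    raw = np.column_stack([stack[n].values[unmasked] for n in fit.layer_names])
    scores = fit.predict_features(fit.featurize(raw))
    out = np.full(geom.shape, np.nan)
    out[unmasked] = np.clip(scores, 0.0, 1.0)
    return geom.copy_with(out)


def predict_at(fit: SdmFit, stack: ClimateStack, points) -> np.ndarray:
    """Scores at (lon, lat) points; NaN for masked/out-of-bounds points."""
    df = extract_at(stack, points)
    ok = (df["in_bounds"] & ~df["masked"]).to_numpy()
    out = np.full(len(df), np.nan)
    if ok.any():
        raw = df.loc[ok, fit.layer_names].to_numpy(float)
        out[ok] = fit.predict_features(fit.featurize(raw))
    return out


# ---------------------------------------------------------------------------
# Serialization (CLI-facing)
# ---------------------------------------------------------------------------

def fit_to_json(fit: SdmFit) -> str:
    params: dict
    if fit.kind == "maxent":
        m = fit.model
        params = {"lambda": m.lambda_.tolist(), "log_z": m.log_z_, "center": m.center_}
    elif fit.kind == "glm":
        m = fit.model
        params = {"terms": list(m.terms_), "coef": m.coef_.tolist()}
    elif fit.kind == "brt":
        m = fit.model
        params = {"base_score": m.base_score_, "learning_rate": m.learning_rate,
                  "trees": m.trees_}
    else:
        raise ValueError(f"unknown fit kind {fit.kind!r}")
    return json.dumps({
        "kind": fit.kind,
        "layer_names": fit.layer_names,
        "term_names": fit.term_names,
        "bg_mean": fit.bg_mean.tolist(),
        "bg_sd": fit.bg_sd.tolist(),
        "quadratic": fit.quadratic,
        "metadata": fit.metadata,
        "parameters": params,
    }, indent=2)


class _FrozenModel:
    """Deserialized predictor reconstructed from the JSON fit schema."""

    def __init__(self, kind: str, params: dict):
        self.kind = kind
        self.params = params

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = self.params
        if self.kind == "maxent":
            return _sigmoid(X @ np.asarray(p["lambda"]) - p["center"])
        if self.kind == "glm":
            Xd = np.column_stack([np.ones(len(X))] + [X[:, j] for j in p["terms"]])
            return _sigmoid(Xd @ np.asarray(p["coef"]))
        score = np.full(len(X), p["base_score"])
        upd = np.empty(len(X))
        for tree in p["trees"]:
            _predict_tree(tree, X, upd, np.arange(len(X)))
            score += p["learning_rate"] * upd
        return _sigmoid(score)


def fit_from_json(text: str) -> SdmFit:
    d = json.loads(text)
    return SdmFit(
        kind=d["kind"],
        model=_FrozenModel(d["kind"], d["parameters"]),
        layer_names=d["layer_names"],
        term_names=d["term_names"],
        bg_mean=np.asarray(d["bg_mean"]),
        bg_sd=np.asarray(d["bg_sd"]),
        quadratic=d["quadratic"],
        metadata=d.get("metadata", {}),
    )
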