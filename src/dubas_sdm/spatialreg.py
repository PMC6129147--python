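"""OLS with VIF screening and geographically weighted regression (GWR).

The infestation–climate linkage is modelled two ways: a global ordinary
least squares fit (with variance-inflation-factor screening of redundant
climate factors), and a GWR fit

    y_i = beta_0(u_i, v_i) + sum_k beta_k(u_i, v_i) x_ik + e_i

where each location (u_i, v_i) gets its own coefficients from weighted least
squares with a distance-kernel weight w_ij = K(d_ij / bandwidth). A binary
infestation response is fitted by least squares (a linear probability
model), matching the use of OLS/GWR directly on presence data.

AIC conventions: OLS AIC = n*log(RSS/n) + 2*(K+2); GWR AIC uses the
effective number of parameters tr(S) (hat-matrix trace) in place of K+1.
These are only ever compared within this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._base import BaseEstimator, check_is_fitted
from .errors import FitError
from .geodata import StationSeries
from .interpolate import IDWInterpolator, local_distances

DEFAULT_FACTORS = ("min_temp", "dew_point", "wind_speed")

#: Default VIF cut-off for redundancy screening (a common GIS convention).
DEFAULT_VIF_MAX = 7.5


@dataclass
class DesignMatrix:
    """Locations, named predictors and a response for the spatial regressions."""

    coords: np.ndarray           # (n, 2) lon/lat
    X: np.ndarray                # (n, K)
    y: np.ndarray                # (n,)
    names: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.y = np.asarray(self.y, dtype=float).ravel()
        n, k = self.X.shape
        if len(self.names) != k:
            raise ValueError("names length must match number of predictors")
        if len(self.coords) != n or len(self.y) != n:
            raise ValueError("coords, X and y must have matching length")
        if k < 1:
            raise ValueError("need at least one predictor")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()
                and np.isfinite(self.coords).all()):
            raise ValueError("design matrix contains missing/non-finite cells")

    @property
    def n(self) -> int:
        return len(self.y)

    def subset(self, names: Sequence[str]) -> "DesignMatrix":
        idx = [self.names.index(n) for n in names]
        return DesignMatrix(self.coords, self.X[:, idx], self.y, list(names))


@dataclass
class OlsResult:
    names: list[str]
    coefficients: np.ndarray     # intercept first
    std_errors: np.ndarray
    p_values: np.ndarray
    r_squared: float
    aic: float
    vif: dict[str, float]
    residuals: np.ndarray = field(repr=False)


def _lstsq(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    if w is not None:
        sw = np.sqrt(w)
        Xw, yw = X * sw[:, None], y * sw
    else:
        Xw, yw = X, y
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    return beta, rank


def _vif(X: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    """VIF_k = 1 / (1 - R^2) of predictor k regressed on the others (+ intercept)."""
    n, k = X.shape
    out = {}
    for j in range(k):
        if k == 1:
            out[names[j]] = 1.0
            continue
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, _ = _lstsq(others, X[:, j])
        resid = X[:, j] - others @ beta
        tss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
        out[names[j]] = float(1.0 / max(1.0 - r2, 1e-12))
    return out


def fit_ols(dm: DesignMatrix) -> OlsResult:
    """Global least-squares fit with VIF diagnostics.

    AIC = n*log(RSS/n) + 2*(K+2), counting the intercept and the error
    variance as parameters.
    """
    n, k = dm.X.shape
    if n <= k + 1:
        raise FitError(f"need n > K+1 observations to fit (n={n}, K={k})")
    Xd = np.column_stack([np.ones(n), dm.X])
    beta, rank = _lstsq(Xd, dm.y)
    if rank < k + 1:
        corr = np.corrcoef(dm.X, rowvar=False)
        pairs = [
            (dm.names[i], dm.names[j])
            for i in range(k) for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise FitError(f"rank-deficient design; collinear columns: {pairs or dm.names}")
    resid = dm.y - Xd @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((dm.y - dm.y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = n - k - 1
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    aic = n * np.log(rss / n) + 2 * (k + 2)
    return OlsResult(
        names=list(dm.names),
        coefficients=beta,
        std_errors=se,
        p_values=pvals,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        aic=float(aic),
        vif=_vif(dm.X, dm.names),
        residuals=resid,
    )


def screen_vif(dm: DesignMatrix, vif_max: float = DEFAULT_VIF_MAX) -> tuple[DesignMatrix, list[str]]:
    """Iteratively drop the highest-VIF predictor until all VIF <= vif_max.

    Returns the reduced design matrix and the removal log (drop order).
    """
    if not vif_max > 1:
        raise ValueError("vif_max must exceed 1")
    names = list(dm.names)
    removed: list[str] = []
    while True:
        sub = dm.subset(names)
        vifs = _vif(sub.X, names)
        worst = max(names, key=lambda n: vifs[n])
        if vifs[worst] <= vif_max:
            return sub, removed
        if len(names) == 1:
            raise FitError("VIF screen would remove every predictor")
        names.remove(worst)
        removed.append(worst)


@dataclass
class GwrResult:
    names: list[str]
    coords: np.ndarray
    coefficients: np.ndarray     # (n, K+1), intercept first
    fitted: np.ndarray
    residuals: np.ndarray
    local_r2: np.ndarray
    r_squared: float             # global, from pooled fitted values
    aic: float
    effective_params: float      # tr(S)
    bandwidth: float
    kernel: str


class GWRRegressor(BaseEstimator):
    """Geographically weighted least squares.

    Parameters
    ----------
    bandwidth : float or None
        Kernel bandwidth in the same degree-equivalent units as the
        distances; None selects it by leave-one-out cross-validation over a
        log-spaced grid spanning the inter-point distance range.
    kernel : {"gaussian", "bisquare"}
    """

    def __init__(self, bandwidth: float | None = None, kernel: str = "gaussian"):
        self.bandwidth = bandwidth
        self.kernel = kernel

    def _weights(self, d: np.ndarray, bw: float) -> np.ndarray:
        if self.kernel == "gaussian":
            return np.exp(-0.5 * (d / bw) ** 2)
        if self.kernel == "bisquare":
            u = d / bw
            return np.where(u < 1, (1 - u**2) ** 2, 0.0)
        raise ValueError(f"unknown kernel {self.kernel!r}")

    def _cv_bandwidth(self, d: np.ndarray, Xd: np.ndarray, y: np.ndarray) -> float:
        off = d[~np.eye(len(d), dtype=bool)]
        lo = max(np.quantile(off, 0.05), 1e-6)
        hi = off.max() * 2
        scores: list[tuple[float, float]] = []
        for bw in np.geomspace(lo, hi, 12):
            w = self._weights(d, bw)
            np.fill_diagonal(w, 0.0)
            sse = 0.0
            ok = True
            for i in range(len(y)):
                try:
                    beta, rank = _lstsq(Xd, y, w[i])
                except np.linalg.LinAlgError:
                    ok = False
                    break
                if rank < Xd.shape[1]:
                    ok = False
                    break
                sse += (y[i] - Xd[i] @ beta) ** 2
            if ok:
                scores.append((bw, sse))
        if not scores:
            return float(hi)
        best = min(s for _, s in scores)
        # prefer the smoothest model whose LOO score is within 5% of the best,
        # so flat CV curves (no spatial signal) do not pick a narrow bandwidth
        return float(max(bw for bw, s in scores if s <= 1.05 * best))

    def fit(self, coords, X, y, names: Sequence[str] | None = None) -> "GWRRegressor":
        dm = DesignMatrix(
            coords, X, y,
            list(names) if names is not None else [f"x{j}" for j in range(np.atleast_2d(np.asarray(X).T).shape[0])],
        )
        n, k = dm.X.shape
        if n <= k + 1:
            raise FitError(f"need n > K+1 observations to fit GWR (n={n}, K={k})")
        Xd = np.column_stack([np.ones(n), dm.X])
        d = local_distances(dm.coords, dm.coords)
        bw = self.bandwidth if self.bandwidth is not None else self._cv_bandwidth(d, Xd, dm.y)
        W = self._weights(d, bw)
        coefs = np.empty((n, k + 1))
        fitted = np.empty(n)
        s_diag = np.empty(n)
        local_r2 = np.empty(n)
        for i in range(n):
            w = W[i]
            sw = np.sqrt(w)
            Xw = Xd * sw[:, None]
            XtWX = Xw.T @ Xw
            try:
                XtWX_inv = np.linalg.inv(XtWX)
            except np.linalg.LinAlgError as e:
                raise FitError(
                    f"GWR local system rank-deficient at location {i} "
                    f"{tuple(dm.coords[i])}; increase bandwidth"
                ) from e
            proj = XtWX_inv @ (Xd * w[:, None]).T      # (k+1, n)
            beta = proj @ dm.y
            coefs[i] = beta
            fitted[i] = Xd[i] @ beta
            s_diag[i] = Xd[i] @ proj[:, i]
            yhat_local = Xd @ beta
            ybar_w = np.average(dm.y, weights=w)
            rss_w = np.sum(w * (dm.y - yhat_local) ** 2)
            tss_w = np.sum(w * (dm.y - ybar_w) ** 2)
            local_r2[i] = np.clip(1.0 - rss_w / tss_w, 0.0, 1.0) if tss_w > 0 else 0.0
        resid = dm.y - fitted
        rss = float(resid @ resid)
        tss = float(np.sum((dm.y - dm.y.mean()) ** 2))
        r2 = float(np.clip(1.0 - rss / tss, 0.0, 1.0)) if tss > 0 else 0.0
        trace_s = float(s_diag.sum())
        aic = n * np.log(rss / n) + 2 * (trace_s + 1)
        self.result_ = GwrResult(
            names=dm.names,
            coords=dm.coords,
            coefficients=coefs,
            fitted=fitted,
            residuals=resid,
            local_r2=local_r2,
            r_squared=r2,
            aic=float(aic),
            effective_params=trace_s,
            bandwidth=float(bw),
            kernel=self.kernel,
        )
        return self

    def predict(self, coords=None) -> np.ndarray:
        check_is_fitted(self, "result_")
        if coords is not None:
            raise NotImplementedError("GWR predicts at its fitted locations only")
        return self.result_.fitted


def fit_gwr(
    dm: DesignMatrix, bandwidth: float | None = None, kernel: str = "gaussian"
) -> GwrResult:
    """Functional wrapper over :class:`GWRRegressor`."""
    est = GWRRegressor(bandwidth=bandwidth, kernel=kernel)
    est.fit(dm.coords, dm.X, dm.y, dm.names)
    return est.result_


def climate_to_locations(
    stations: Sequence[StationSeries],
    locations,
    year: int,
    response=None,
    factors: Sequence[str] = DEFAULT_FACTORS,
    power: float = 2.0,
) -> DesignMatrix:
    """IDW-carry annual station climate means to target locations.

    For each factor, the stations' annual means for ``year`` are interpolated
    to the locations with inverse-distance weighting; a location collocated
    with a station inherits that station's values exactly. ``response`` (the
    per-location infestation indicator/index) fills the design matrix's y;
    zeros are used if omitted.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    means = []
    coords = []
    for st in stations:
        m = st.annual_means(year)
        if m is not None:
            means.append(m)
            coords.append((st.longitude, st.latitude))
    if not means:
        raise FitError(f"no station data for year {year}")
    coords = np.asarray(coords)
    cols = {}
    if len(coords) == 1:
        for f in factors:
            cols[f] = np.full(len(locations), means[0][f])
    else:
        for f in factors:
            vals = np.array([m[f] for m in means])
            cols[f] = IDWInterpolator(power=power).fit(coords, vals).predict(locations)
    X = np.column_stack([cols[f] for f in factors])
    y = np.zeros(len(locations)) if response is None else np.asarray(response, dtype=float)
    return DesignMatrix(locations, X, y, list(factors))


def gwr_summary_table(results: dict[int, tuple[OlsResult, GwrResult]]) -> pd.DataFrame:
    """Per-year table of factors kept, OLS R2/AIC and GWR R2/AIC."""
    rows = []
    for year, (ols, gwr) in sorted(results.items()):
        rows.append({
            "year": year,
            "factors": ",".join(ols.names),
            "ols_r2": ols.r_squared,
            "ols_aic": ols.aic,
            "gwr_r2": gwr.r_squared,
            "gwr_aic": gwr.aic,
        })
    return pd.DataFrame(rows)
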