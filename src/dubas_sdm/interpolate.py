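"""Spatial interpolators: inverse-distance weighting and ordinary kriging.

Both are exact interpolators (IDW by its weight singularity at data points,
kriging when the nugget is zero) and both are used twice in the pipeline:
IDW carries station climate to infested locations, and kriging with a linear
semivariogram turns annual per-cell record counts into hotspot surfaces.

Distances are computed on a local equirectangular approximation (longitude
differences scaled by cos of the mean latitude); at a study extent of a few
degrees the error versus geodesics is negligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._base import BaseEstimator, check_is_fitted
from .errors import GeometryError
from .geodata import OccurrenceTable, RasterGrid

logger = logging.getLogger(__name__)

#: Below this separation (degrees) a target is considered coincident with a sample.
COINCIDENT_EPS = 1e-9


def local_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise distances (degree-equivalents) between (lon, lat) arrays."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    coslat = np.cos(np.deg2rad(np.concatenate([a[:, 1], b[:, 1]]).mean()))
    dx = (a[:, None, 0] - b[None, :, 0]) * coslat
    dy = a[:, None, 1] - b[None, :, 1]
    return np.hypot(dx, dy)


def _check_samples(coords: np.ndarray, values: np.ndarray) -> None:
    if len(coords) == 0:
        raise ValueError("at least one sample is required")
    if not np.isfinite(values).all():
        raise ValueError("sample values must be finite")
    d = local_distances(coords, coords)
    np.fill_diagonal(d, np.inf)
    dup = np.argwhere(d < COINCIDENT_EPS)
    for i, j in dup:
        if i < j and values[i] != values[j]:
            raise ValueError(
                f"duplicate sample locations with different values: "
                f"#{i} {tuple(coords[i])}={values[i]} vs #{j} {tuple(coords[j])}={values[j]}"
            )


class IDWInterpolator(BaseEstimator):
    """Inverse-distance-weighted interpolation.

    Weights decay as ``distance ** -power`` (default 2, the common GIS
    default). A target within :data:`COINCIDENT_EPS` of a sample returns that
    sample's value exactly. Predictions are convex combinations of the sample
    values and hence bounded by their range.
    """

    def __init__(self, power: float = 2.0):
        if not power > 0:
            raise ValueError("power must be positive")
        self.power = power

    def fit(self, coords, values) -> "IDWInterpolator":
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        values = np.asarray(values, dtype=float)
        _check_samples(coords, values)
        self.coords_ = coords
        self.values_ = values
        return self

    def predict(self, targets) -> np.ndarray:
        check_is_fitted(self, "coords_")
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        d = local_distances(targets, self.coords_)
        out = np.empty(len(targets))
        exact = d < COINCIDENT_EPS
        with np.errstate(divide="ignore"):
            w = d ** (-self.power)
        for i in range(len(targets)):
            if exact[i].any():
                out[i] = self.values_[np.argmax(exact[i])]
            else:
                wi = w[i]
                out[i] = np.dot(wi, self.values_) / wi.sum()
        return out

    def predict_grid(self, geometry: RasterGrid) -> RasterGrid:
        lon, lat = geometry.cell_centers()
        vals = self.predict(np.column_stack([lon.ravel(), lat.ravel()]))
        return geometry.copy_with(vals.reshape(geometry.shape))


@dataclass(frozen=True)
class Variogram:
    """Linear semivariogram gamma(h) = nugget + slope * h (gamma(0) = 0)."""

    slope: float = 1.0
    nugget: float = 0.0
    model: str = "linear"

    def __post_init__(self) -> None:
        if self.model != "linear":
            raise ValueError("only the linear semivariogram model is supported")
        if not self.slope > 0:
            raise ValueError("variogram slope must be positive")
        if self.nugget < 0:
            raise ValueError("nugget must be non-negative")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return np.where(h <= 0, 0.0, self.nugget + self.slope * h)


class OrdinaryKriging(BaseEstimator):
    """Ordinary kriging under a linear semivariogram.

    Solves the standard system ``[[Gamma, 1], [1', 0]] [w; mu] = [gamma*; 1]``
    per target; with nugget 0 the predictor is exact at sample locations with
    zero kriging variance.
    """

    def __init__(self, variogram: Variogram = Variogram()):
        self.variogram = variogram

    def fit(self, coords, values) -> "OrdinaryKriging":
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        values = np.asarray(values, dtype=float)
        if len(coords) < 2:
            raise ValueError("ordinary kriging needs at least 2 samples")
        _check_samples(coords, values)
        n = len(coords)
        gamma = self.variogram(local_distances(coords, coords))
        lhs = np.zeros((n + 1, n + 1))
        lhs[:n, :n] = gamma
        lhs[:n, n] = 1.0
        lhs[n, :n] = 1.0
        try:
            self._lu_ = np.linalg.inv(lhs)
        except np.linalg.LinAlgError as e:
            raise ValueError(
                "singular kriging system; try a positive nugget"
            ) from e
        self.coords_ = coords
        self.values_ = values
        return self

    def predict(self, targets, return_variance: bool = False):
        check_is_fitted(self, "coords_")
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        n = len(self.coords_)
        d = local_distances(targets, self.coords_)
        rhs = np.ones((len(targets), n + 1))
        rhs[:, :n] = self.variogram(d)
        sol = rhs @ self._lu_.T            # rows: [w_1..w_n, mu]
        preds = sol[:, :n] @ self.values_
        if not return_variance:
            return preds
        var = np.einsum("ij,ij->i", sol, rhs)
        return preds, np.maximum(var, 0.0)

    def predict_grid(self, geometry: RasterGrid, return_variance: bool = False):
        lon, lat = geometry.cell_centers()
        pts = np.column_stack([lon.ravel(), lat.ravel()])
        if return_variance:
            v, s2 = self.predict(pts, return_variance=True)
            return (
                geometry.copy_with(v.reshape(geometry.shape)),
                geometry.copy_with(s2.reshape(geometry.shape)),
            )
        v = self.predict(pts)
        return geometry.copy_with(v.reshape(geometry.shape))


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def idw(samples, targets, power: float = 2.0):
    """Functional IDW: samples as (lon, lat, value) triples."""
    samples = np.asarray(samples, dtype=float)
    est = IDWInterpolator(power=power).fit(samples[:, :2], samples[:, 2])
    if isinstance(targets, RasterGrid):
        return est.predict_grid(targets)
    return est.predict(targets)


def ordinary_kriging(samples, targets, variogram: Variogram = Variogram()):
    """Functional ordinary kriging: returns (values, kriging variances)."""
    samples = np.asarray(samples, dtype=float)
    est = OrdinaryKriging(variogram=variogram).fit(samples[:, :2], samples[:, 2])
    if isinstance(targets, RasterGrid):
        return est.predict_grid(targets, return_variance=True)
    return est.predict(targets, return_variance=True)


# ---------------------------------------------------------------------------
# Hotspot surfaces
# ---------------------------------------------------------------------------

def _count_grid(occurrences: OccurrenceTable, year: int, geometry: RasterGrid) -> np.ndarray:
    sub = occurrences.filter_years([year])
    counts = np.zeros(geometry.shape)
    if len(sub):
        row, col, inside = geometry.index_of(sub.lon, sub.lat)
        np.add.at(counts, (row[inside], col[inside]), 1.0)
    return counts


def hotspot_surface(
    occurrences: OccurrenceTable,
    year: int,
    geometry: RasterGrid,
    variogram: Variogram = Variogram(),
    max_samples: int = 300,
) -> RasterGrid:
    """Kriged annual record-density surface.

    Per-cell record counts for the year are the kriging samples: every
    occupied cell contributes its count, padded with a deterministic
    regular-stride subset of empty cells (value 0) so the sample set stays
    small and the system well-posed. Fewer than 2 records for the year yields
    an all-masked sentinel surface with a warning.
    """
    sub = occurrences.filter_years([year])
    if len(sub) < 2:
        logger.warning("hotspot_surface: fewer than 2 records for year %s; empty surface", year)
        return geometry.copy_with(
            np.full(geometry.shape, np.nan), np.ones(geometry.shape, dtype=bool)
        )
    counts = _count_grid(occurrences, year, geometry)
    lon, lat = geometry.cell_centers()
    occupied = counts > 0
    empty_idx = np.flatnonzero(~occupied.ravel() & ~geometry.nodata_mask.ravel())
    n_pad = max(max_samples - int(occupied.sum()), 2)
    if len(empty_idx) > n_pad:
        stride = len(empty_idx) // n_pad
        empty_idx = empty_idx[::stride][:n_pad]
    sel = np.flatnonzero(occupied.ravel())
    idx = np.concatenate([sel, empty_idx])
    coords = np.column_stack([lon.ravel()[idx], lat.ravel()[idx]])
    values = counts.ravel()[idx]
    est = OrdinaryKriging(variogram=variogram).fit(coords, values)
    return est.predict_grid(geometry)


#: Class codes of a hotspot change map.
CHANGE_STABLE_LOW, CHANGE_GAINED, CHANGE_LOST, CHANGE_STABLE_HIGH = 0, 1, 2, 3
CHANGE_LABELS = {0: "stable-low", 1: "gained", 2: "lost", 3: "stable-high"}


def hotspot_change(
    surface_a: RasterGrid, surface_b: RasterGrid, high_quantile: float = 0.9
) -> RasterGrid:
    """Classify cells by crossing the hotspot threshold between two years.

    The threshold is the ``high_quantile`` quantile of the first (reference)
    surface's unmasked values, applied to both surfaces; cells are labelled
    gained/lost/stable-high/stable-low (codes in :data:`CHANGE_LABELS`).
    """
    if not surface_a.same_geometry(surface_b):
        raise GeometryError("hotspot surfaces have different geometry")
    if not 0 < high_quantile < 1:
        raise ValueError("high_quantile must be in (0, 1)")
    mask = surface_a.nodata_mask | surface_b.nodata_mask
    ref = surface_a.values[~surface_a.nodata_mask]
    thr = np.quantile(ref, high_quantile)
    high_a = surface_a.values >= thr
    high_b = surface_b.values >= thr
    codes = np.full(surface_a.shape, CHANGE_STABLE_LOW, dtype=float)
    codes[high_a & high_b] = CHANGE_STABLE_HIGH
    codes[~high_a & high_b] = CHANGE_GAINED
    codes[high_a & ~high_b] = CHANGE_LOST
    codes[mask] = np.nan
    return surface_a.copy_with(codes, mask)
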