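"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate the ingredients of a desert date-palm pest study
without any download: spatially autocorrelated, mutually correlated climate
layers over a northern-Oman-sized extent; a known "true" suitability surface
(sharp and rare, as cultivated palm valleys are within the region); presence
records sampled proportionally to that truth times a survey-effort kernel;
and daily weather-station series whose infestation response depends weakly,
with spatially varying slopes, on dew point, minimum temperature and wind
speed.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geodata import ClimateStack, OccurrenceTable, RasterGrid, StationSeries

#: Default study extent: lon 56.0-59.5 E, lat 22.0-24.5 N at 0.05 degree cells.
DEFAULT_EXTENT = dict(x_origin=56.0, y_origin=22.0, cell_size=0.05)

DEFAULT_YEARS = (2007, 2008, 2009, 2010, 2011, 2015)


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    The defaults define the package's reference scenario: a strong, sharply
    localized true niche (most of the extent near-unsuitable) driven by two
    of ten correlated climate layers, and survey effort biased toward a
    kernel in the middle of the extent.
    """

    seed: int = 0
    n_rows: int = 50
    n_cols: int = 70
    n_layers: int = 10
    layer_correlation: float = 0.3
    spatial_range: float = 5.0          # cells; Gaussian smoothing length
    true_intercept: float = -18.0
    true_coefficients: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"bio2": (30.0, -24.0), "bio5": (24.0, -18.0)}
    )
    bias_center: tuple[float, float] = (57.5, 23.3)
    bias_sd: float | None = 0.7         # degrees; None disables survey bias
    n_presence: int = 400
    noise_sd: float = 1.0
    years: Sequence[int] = DEFAULT_YEARS
    x_origin: float = DEFAULT_EXTENT["x_origin"]
    y_origin: float = DEFAULT_EXTENT["y_origin"]
    cell_size: float = DEFAULT_EXTENT["cell_size"]

    def __post_init__(self) -> None:
        if self.spatial_range < 1:
            raise ValueError("spatial_range must be >= 1 cell")
        if not 0 <= self.layer_correlation < 1:
            raise ValueError("layer_correlation must be in [0, 1)")
        if self.n_presence > self.n_rows * self.n_cols:
            raise ValueError("n_presence exceeds the number of cells")

    def layer_names(self) -> list[str]:
        return [f"bio{i + 1}" for i in range(self.n_layers)]

    def rng(self, *stream: int) -> np.random.Generator:
        """Deterministic per-stream generator derived from the master seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, *stream]))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Standardized Gaussian random field: smoothed white noise, unit variance."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=scale, mode="reflect")
    return (f - f.mean()) / f.std()


def gen_climate_stack(cfg: SynthConfig) -> ClimateStack:
    """Spatially autocorrelated, cross-correlated climate layers.

    Each layer mixes a shared random field (weight ``sqrt(layer_correlation)``)
    with an independent one, so the expected pairwise Pearson correlation is
    ``layer_correlation``; layers are given distinct affine units so that
    downstream standardization is exercised.
    """
    rng = cfg.rng(1)
    shape = (cfg.n_rows, cfg.n_cols)
    shared = _smooth_field(rng, shape, cfg.spatial_range)
    rho = cfg.layer_correlation
    mask = np.zeros(shape, dtype=bool)
    layers: dict[str, RasterGrid] = {}
    for i, name in enumerate(cfg.layer_names()):
        own = _smooth_field(rng, shape, cfg.spatial_range)
        z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        # distinct per-layer units (offsets/scales loosely temperature/precip-like)
        values = (10.0 + 3.0 * i) + (2.0 + (i % 4)) * z
        layers[name] = RasterGrid(values, mask.copy(), cfg.x_origin, cfg.y_origin, cfg.cell_size)
    return ClimateStack(layers)


def _standardized_layers(stack: ClimateStack, names: Sequence[str]) -> dict[str, np.ndarray]:
    out = {}
    for name in names:
        g = stack[name]
        v = g.values[~g.nodata_mask]
        out[name] = (g.values - v.mean()) / v.std()
    return out


def gen_true_suitability(stack: ClimateStack, cfg: SynthConfig) -> RasterGrid:
    """Known true suitability in [0, 1].

    Logistic transform of ``intercept + sum(linear*z + quadratic*z^2)`` over
    the standardized layers named in ``true_coefficients``.
    """
    names = list(cfg.true_coefficients)
    z = _standardized_layers(stack, names)
    score = np.full(stack.geometry.shape, cfg.true_intercept, dtype=float)
    for name in names:
        lin, quad = cfg.true_coefficients[name]
        score = score + lin * z[name] + quad * z[name] ** 2
    from scipy.special import expit

    suit = expit(score)
    geom = stack.geometry
    suit = np.where(geom.nodata_mask, np.nan, suit)
    return geom.copy_with(suit)


def _bias_kernel(truth: RasterGrid, cfg: SynthConfig) -> np.ndarray:
    if cfg.bias_sd is None:
        return np.ones(truth.shape)
    lon, lat = truth.cell_centers()
    d2 = (lon - cfg.bias_center[0]) ** 2 + (lat - cfg.bias_center[1]) ** 2
    return np.exp(-0.5 * d2 / cfg.bias_sd**2)


def sample_occurrences(truth: RasterGrid, cfg: SynthConfig) -> OccurrenceTable:
    """Presence records drawn with probability proportional to truth x survey effort.

    Cells are sampled with replacement; each record is jittered uniformly
    within its cell and assigned a year uniformly from ``cfg.years``.
    """
    rng = cfg.rng(2)
    p = np.where(truth.nodata_mask, 0.0, np.nan_to_num(truth.values)) * _bias_kernel(truth, cfg)
    flat = p.ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("true suitability is zero everywhere; cannot sample presences")
    idx = rng.choice(flat.size, size=cfg.n_presence, replace=True, p=flat / total)
    rows, cols = np.unravel_index(idx, truth.shape)
    cs = truth.cell_size
    jitter = rng.uniform(0, cs, size=(cfg.n_presence, 2))
    lon = truth.x_origin + cols * cs + jitter[:, 0]
    lat = truth.y_origin + (truth.n_rows - 1 - rows) * cs + jitter[:, 1]
    years = rng.choice(np.asarray(list(cfg.years), dtype=int), size=cfg.n_presence)
    return OccurrenceTable(pd.DataFrame({
        "longitude": lon, "latitude": lat, "year": years,
        "presence": 1, "weight": 1.0,
    }))


#: Station-series factors that may carry a spatially varying infestation effect.
STATION_FACTORS = ("dew_point", "min_temp", "wind_speed")

#: Default spatially varying slopes (base, west-east gradient) per factor,
#: sized so the infestation signal is weak: GWR global R-squared lands in
#: roughly 0.05-0.15 under noise_sd = 1.
DEFAULT_STATION_EFFECT: dict[str, tuple[float, float]] = {
    "dew_point": (0.25, 0.25),
    "min_temp": (0.12, 0.10),
}


def gen_station_series(
    cfg: SynthConfig,
    n_stations: int,
    n_days: int,
    effect: Mapping[str, tuple[float, float]] | None = None,
    year: int = 2009,
) -> tuple[list[StationSeries], pd.DataFrame]:
    """Weather stations plus an infestation table with a weak spatial signal.

    Stations are placed uniformly over the extent. Each daily series has a
    mild seasonal cycle plus noise with ``min <= mean <= max`` enforced. The
    infestation index at station *i* is::

        y_i = sum_f slope_f(u_i) * z_if + noise,   slope_f(u) = base_f + grad_f * s(u)

    where ``z_if`` is the station's standardized annual mean of factor *f* and
    ``s(u)`` is the station longitude rescaled to [-0.5, 0.5]. ``effect`` maps
    factor name -> (base, gradient); factors absent from the map have zero
    effect. A binary ``presence`` column thresholds the index at its median.
    """
    if effect is None:
        effect = DEFAULT_STATION_EFFECT
    unknown = [f for f in effect if f not in STATION_FACTORS]
    if unknown:
        raise ValueError(f"unknown station factors in effect map: {unknown}")
    rng = cfg.rng(3)
    width = cfg.n_cols * cfg.cell_size
    height = cfg.n_rows * cfg.cell_size
    lon = cfg.x_origin + rng.uniform(0, width, n_stations)
    lat = cfg.y_origin + rng.uniform(0, height, n_stations)

    dates = pd.date_range(f"{year}-01-01", periods=n_days, freq="D")
    doy = np.asarray(dates.dayofyear, dtype=float) if n_days else np.empty(0)
    stations: list[StationSeries] = []
    annual = {f: np.zeros(n_stations) for f in STATION_FACTORS}
    for i in range(n_stations):
        seasonal = 10.0 * np.sin(2 * np.pi * (doy - 120) / 365.25)
        mean_t = 28.0 + 2.0 * rng.standard_normal() + seasonal + rng.normal(0, 1.5, n_days)
        spread = np.abs(rng.normal(5.0, 1.0, n_days)) + 0.5
        df = pd.DataFrame({
            "date": dates,
            "mean_temp": mean_t,
            "min_temp": mean_t - spread,
            "max_temp": mean_t + spread,
            "dew_point": 12.0 + 3.0 * rng.standard_normal() + rng.normal(0, 2.0, n_days),
            "wind_speed": np.abs(8.0 + 2.0 * rng.standard_normal() + rng.normal(0, 2.0, n_days)),
            "precipitation": np.maximum(rng.normal(0.1, 1.0, n_days), 0.0),
        })
        stations.append(StationSeries(f"S{i:04d}", float(lon[i]), float(lat[i]), df))
        if n_days:
            annual["dew_point"][i] = df.dew_point.mean()
            annual["min_temp"][i] = df.min_temp.mean()
            annual["wind_speed"][i] = df.wind_speed.mean()

    s = (lon - cfg.x_origin) / width - 0.5
    y = rng.normal(0, cfg.noise_sd, n_stations)
    true_slopes = {}
    for f, (base, grad) in effect.items():
        slope = base + grad * s
        true_slopes[f] = slope
        if n_days:
            z = (annual[f] - annual[f].mean()) / (annual[f].std() or 1.0)
            y = y + slope * z
    infest = pd.DataFrame({
        "longitude": lon, "latitude": lat, "year": year,
        "infestation": y,
        "presence": (y > np.median(y)).astype(int) if n_stations else [],
    })
    for f, slope in true_slopes.items():
        infest[f"true_slope_{f}"] = slope
    return stations, infest


def make_synthetic_record_file(path, n_total: int = 2000, seed: int = 0) -> None:
    """Write a synthetic stand-in for a deposited multi-year pest record file.

    Synthetic data: this is NOT the deposited survey dataset, only a CSV with
    the same documented structure — records over years 2007-2011, 2015 and
    2016 across the 56-59.5 E longitude range — constructed so that filtering
    to the survey years 2007-2011 and 2015 yields 1,708 records of which
    1,196 fall in the 56.5-59.0 E calibration band.
    """
    rng = np.random.default_rng(seed)
    n_keep = 1708
    n_train = 1196
    n_test = n_keep - n_train
    n_extra = max(n_total - n_keep, 0)

    def band(lo, hi, n):
        return rng.uniform(lo, hi, n)

    lon = np.concatenate([
        band(56.5, 59.0, n_train),                       # calibration band
        band(56.0, 56.5, n_test // 2),                   # western validation band
        band(59.0, 59.5, n_test - n_test // 2),          # eastern validation band
        band(56.0, 59.5, n_extra),                       # later field records
    ])
    lat = rng.uniform(22.0, 24.5, lon.size)
    years = np.concatenate([
        rng.choice([2007, 2008, 2009, 2010, 2011, 2015], n_keep),
        np.full(n_extra, 2016),
    ])
    order = rng.permutation(lon.size)
    pd.DataFrame({
        "longitude": lon[order], "latitude": lat[order],
        "year": years[order], "presence": 1,
    }).to_csv(path, index=False)
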