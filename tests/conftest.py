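import numpy as np
import pandas as pd
import pytest

from dubas_sdm.geodata import ClimateStack, OccurrenceTable, RasterGrid
from dubas_sdm import synthdata


@pytest.fixture
def small_grid() -> RasterGrid:
    """4x5 grid over lon [56, 56.5), lat [23, 23.4), one masked cell."""
    rng = np.random.default_rng(42)
    values = rng.normal(size=(4, 5))
    mask = np.zeros((4, 5), dtype=bool)
    mask[1, 2] = True
    return RasterGrid(values, mask, x_origin=56.0, y_origin=23.0, cell_size=0.1)


@pytest.fixture
def synth_cfg() -> synthdata.SynthConfig:
    return synthdata.SynthConfig(seed=0)


@pytest.fixture
def small_cfg() -> synthdata.SynthConfig:
    """Reduced-size scenario for fast model fits."""
    return synthdata.SynthConfig(seed=3, n_rows=30, n_cols=40, n_layers=5,
                                 true_coefficients={"bio2": (30.0, -24.0)},
                                 true_intercept=-10.0, n_presence=150)


@pytest.fixture
def small_stack(small_cfg) -> ClimateStack:
    return synthdata.gen_climate_stack(small_cfg)


@pytest.fixture
def small_truth(small_stack, small_cfg) -> RasterGrid:
    return synthdata.gen_true_suitability(small_stack, small_cfg)


@pytest.fixture
def small_occ(small_truth, small_cfg) -> OccurrenceTable:
    return synthdata.sample_occurrences(small_truth, small_cfg)


def make_occ(lons, lats, years=None, presence=1) -> OccurrenceTable:
    lons = np.asarray(lons, dtype=float)
    years = np.full(len(lons), 2009) if years is None else np.asarray(years)
    return OccurrenceTable(pd.DataFrame({
        "longitude": lons, "latitude": np.asarray(lats, dtype=float),
        "year": years, "presence": presence,
    }))
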