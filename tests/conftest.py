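import numpy as np
import pandas as pd
import pytest

from airburden.grid import GridSpec, GriddedField, RegionMask, IMF_REGIONS
from airburden.synth import (ADULT_AGE_GROUPS, ENDPOINTS, PopulationGrid,
                             SyntheticConfig, default_age_pyramid)


@pytest.fixture
def small_grid():
    return GridSpec.global_grid(30.0, 30.0)  # 6 x 12 global


@pytest.fixture
def demo_cfg(small_grid):
    return SyntheticConfig(seed=7, grid=small_grid, station_count=40)


@pytest.fixture
def uniform_population(small_grid):
    """1e8 people spread evenly over cells, default age pyramid."""
    n = small_grid.shape[0] * small_grid.shape[1]
    counts = GriddedField(small_grid, np.full(small_grid.shape, 1e8 / n),
                          units="persons", kind="extensive")
    return PopulationGrid(counts, default_age_pyramid())


@pytest.fixture
def single_region_mask(small_grid):
    return RegionMask(small_grid, np.zeros(small_grid.shape, dtype=int),
                      {0: ("China", "developing")})


def make_tables(bmr_rate=0.01, myll_years=12.0):
    """Uniform BMR/MYLL tables across every region, endpoint and age —
    the configuration for which burden has an analytic closed form."""
    rows = [
        (name, ep, age, bmr_rate, myll_years)
        for name, _ in IMF_REGIONS.values()
        for ep in ENDPOINTS
        for age in ADULT_AGE_GROUPS
    ]
    df = pd.DataFrame(rows, columns=["region", "endpoint", "age", "bmr", "myll"])
    return df[["region", "endpoint", "age", "bmr"]], df[["region", "endpoint", "age", "myll"]]


@pytest.fixture
def uniform_tables():
    return make_tables()
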