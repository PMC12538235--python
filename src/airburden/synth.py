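"""Seeded synthetic inputs for the exposure-to-burden pipeline.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes: non-negative concentration
fields (lognormal background plus Gaussian plumes over regional hotspots),
spatially clustered population with a prescribed global total, age-fraction
vectors summing to one, endpoint/age baseline-mortality and mean-YLL
tables, station observations drawn from a truth field, emission inventories
with prescribed area-integrals, and a tiled stand-in for the 11-region
mask.  All generators are pure functions of (config, seed): one global seed
feeds an independent spawned RNG stream per generator, so adding a
generator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .grid import GridSpec, GriddedField, RegionMask, IMF_REGIONS, cell_areas, global_integral

#: 5-year age groups; the hazard models apply to adults (>= 25)
AGE_GROUPS = [f"{a}-{a + 4}" for a in range(0, 80, 5)] + ["80+"]
ADULT_AGE_GROUPS = [g for g in AGE_GROUPS if int(g.split("-")[0].rstrip("+")) >= 25]
ENDPOINTS = ("NCD+LRI", "COPD")

# stream ids: stable per generator so streams stay independent
_STREAMS = {
    "concentration": 0,
    "population": 1,
    "bmr": 2,
    "stations": 3,
    "inventory": 4,
    "hotspots": 5,
    "mask": 6,
}


@dataclass
class SyntheticConfig:
    """Knobs for all generators.

    Defaults describe a plausible 2015-like world on a coarse demo grid:
    a ~10 μg/m³ lognormal PM2.5 background with strong regional plumes,
    7.3 billion people (mid-2015 global population) of whom ~54% live in
    urban clusters, and station networks with ~10% observational noise.
    """

    seed: int = 0
    grid: GridSpec = dc_field(default_factory=lambda: GridSpec.global_grid(5.0, 5.0))
    n_hotspots: int = 8
    background_median: float = 10.0
    background_sigma_log: float = 0.5
    hotspot_amplitude: float = 30.0
    hotspot_radius_deg: float = 12.0
    population_total: float = 7.3e9
    urban_fraction: float = 0.54
    station_count: int = 100
    obs_noise_cv: float = 0.10
    age_decay: float = 0.93  # geometric population decay per 5-year group

    def __post_init__(self):
        for name in ("background_median", "hotspot_radius_deg", "population_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("urban_fraction",):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("background_sigma_log", "hotspot_amplitude", "obs_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


def _sphere_points(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """n points uniform on the sphere (cos-lat weighted in latitude)."""
    lat = np.rad2deg(np.arcsin(rng.uniform(-1, 1, n)))
    lon = rng.uniform(-180, 180, n)
    return lat, lon


def _plumes(grid: GridSpec, centers: tuple[np.ndarray, np.ndarray],
            amplitude: float, radius_deg: float) -> np.ndarray:
    """Sum of Gaussian plumes; great-circle-ish distance via chord length."""
    glat, glon = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    out = np.zeros(grid.shape)
    for clat, clon in zip(*centers):
        dlon = (glon - clon + 180) % 360 - 180
        d2 = (glat - clat) ** 2 + (np.cos(np.deg2rad((glat + clat) / 2)) * dlon) ** 2
        out += amplitude * np.exp(-d2 / (2 * radius_deg**2))
    return out


def gen_concentration_field(cfg: SyntheticConfig, units: str = "ug/m3",
                            case: str = "") -> GriddedField:
    """Lognormal background exp(N(ln median, σ²)) plus ``n_hotspots``
    Gaussian plumes of the configured amplitude.  Non-negative by
    construction and bit-reproducible for a fixed seed."""
    rng = cfg.rng("concentration")
    background = np.exp(
        rng.normal(np.log(cfg.background_median), cfg.background_sigma_log, cfg.grid.shape)
    )
    centers = _sphere_points(cfg.rng("hotspots"), cfg.n_hotspots)
    vals = background + _plumes(cfg.grid, centers, cfg.hotspot_amplitude,
                                cfg.hotspot_radius_deg)
    return GriddedField(cfg.grid, vals, units=units, kind="intensive", case=case)


def gen_case_pair(cfg: SyntheticConfig, anthropogenic_share: float | np.ndarray,
                  units: str = "ug/m3", case: str = "CASE") -> tuple[GriddedField, GriddedField]:
    """A (case, zero-anthropogenic) field pair with OFF = case × (1 − share)
    cellwise; share may vary spatially.  OFF ≤ case wherever share ≥ 0."""
    share = np.asarray(anthropogenic_share, dtype=float)
    case_f = gen_concentration_field(cfg, units=units, case=case)
    off_vals = case_f.values * (1.0 - share)
    off = GriddedField(cfg.grid, off_vals, units=units, kind="intensive", case="OFF")
    return case_f, off


@dataclass
class PopulationGrid:
    """Per-cell person counts plus the 5-year age-fraction table.

    ``age_fractions`` is indexed by AGE_GROUPS and sums to 1; the same
    pyramid applies to every cell (a per-cell table adds nothing the tests
    exercise and the burden equations only need the product)."""

    counts: GriddedField
    age_fractions: pd.Series

    def __post_init__(self):
        if abs(self.age_fractions.sum() - 1.0) > 1e-9:
            raise ValueError("age fractions must sum to 1")
        if (self.age_fractions < 0).any():
            raise ValueError("age fractions must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.values.sum())

    def counts_for_age(self, group: str) -> np.ndarray:
        return self.counts.values * float(self.age_fractions[group])


def default_age_pyramid(decay: float = 0.93) -> pd.Series:
    w = decay ** np.arange(len(AGE_GROUPS))
    return pd.Series(w / w.sum(), index=AGE_GROUPS, name="fraction")


def gen_population(cfg: SyntheticConfig) -> PopulationGrid:
    """Clustered population summing exactly to ``population_total``.

    ``urban_fraction`` of the mass sits in Gaussian point-spreads around
    the hotspot centers (urban populations co-locate with emission
    plumes); the remainder is spread uniformly per unit area."""
    areas = cell_areas(cfg.grid).values
    rural = areas / areas.sum()
    if cfg.urban_fraction > 0:
        centers = _sphere_points(cfg.rng("population"), max(cfg.n_hotspots, 1))
        urban = _plumes(cfg.grid, centers, 1.0, cfg.hotspot_radius_deg / 2) * areas
        urban_sum = urban.sum()
        urban = urban / urban_sum if urban_sum > 0 else rural
    else:
        urban = rural
    density = (1 - cfg.urban_fraction) * rural + cfg.urban_fraction * urban
    counts = density * cfg.population_total
    counts *= cfg.population_total / counts.sum()  # exact total
    return PopulationGrid(
        GriddedField(cfg.grid, counts, units="persons", kind="extensive"),
        default_age_pyramid(cfg.age_decay),
    )


def gen_bmr_and_myll(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline mortality rates and mean YLL per (region, endpoint, age).

    Rates rise geometrically with age (mortality roughly doubles per
    decade) and stay within [0, 0.5] deaths·person⁻¹·yr⁻¹; mean YLL falls
    with age toward a residual ~5 years at 80+.  Small seeded per-region
    multipliers mimic regional heterogeneity without breaking either
    monotonicity."""
    rng = cfg.rng("bmr")
    regions = [name for name, _ in IMF_REGIONS.values()]
    base = {"NCD+LRI": 2.0e-3, "COPD": 2.0e-4}
    rows = []
    for region in regions:
        region_scale = rng.uniform(0.7, 1.3)
        for endpoint in ENDPOINTS:
            for k, age in enumerate(ADULT_AGE_GROUPS):
                rate = min(base[endpoint] * region_scale * 1.45**k, 0.5)
                midpoint = 27.5 + 5 * k if age != "80+" else 85.0
                myll = max(86.0 - midpoint, 5.0)
                rows.append((region, endpoint, age, rate, myll))
    df = pd.DataFrame(rows, columns=["region", "endpoint", "age", "bmr", "myll"])
    bmr = df[["region", "endpoint", "age", "bmr"]]
    myll = df[["region", "endpoint", "age", "myll"]]
    return bmr, myll


def gen_stations(cfg: SyntheticConfig, truth: GriddedField,
                 network: str = "SYN") -> pd.DataFrame:
    """Station table (lat, lon, value, network) with value = containing-cell
    truth × (1 + ε), ε ~ N(0, cv²) truncated at −0.9 so values stay
    positive."""
    rng = cfg.rng("stations")
    n = cfg.station_count
    lats = rng.uniform(truth.grid.lat_bounds[0], truth.grid.lat_bounds[-1], n)
    lons = rng.uniform(truth.grid.lon_bounds[0], truth.grid.lon_bounds[-1], n)
    ii = np.clip(np.searchsorted(truth.grid.lat_bounds, lats, side="right") - 1,
                 0, truth.grid.shape[0] - 1)
    jj = np.clip(np.searchsorted(truth.grid.lon_bounds, lons, side="right") - 1,
                 0, truth.grid.shape[1] - 1)
    eps = np.maximum(rng.normal(0.0, cfg.obs_noise_cv, n) if cfg.obs_noise_cv > 0
                     else np.zeros(n), -0.9)
    vals = truth.values[ii, jj] * (1.0 + eps)
    return pd.DataFrame({"lat": lats, "lon": lons, "value": vals,
                         "network": network})


def gen_inventory(cfg: SyntheticConfig,
                  species_totals: dict[str, float],
                  year: int = 2015) -> dict[str, GriddedField]:
    """Per-species emission-flux fields (kg m⁻² s⁻¹) whose area-integrals
    equal the prescribed Tg/yr totals exactly (random positive pattern,
    normalized)."""
    from .inventory import seconds_in_year  # local import avoids a cycle

    rng = cfg.rng("inventory")
    areas = cell_areas(cfg.grid).values
    T = seconds_in_year(year)
    out = {}
    for species, total_tg in species_totals.items():
        if total_tg < 0:
            raise ValueError("species totals must be >= 0")
        pattern = rng.lognormal(0.0, 1.0, cfg.grid.shape)
        mass_kg = total_tg * 1e9
        flux = pattern * (mass_kg / np.sum(pattern * areas * T))
        out[species] = GriddedField(cfg.grid, flux, units="kg m-2 s-1",
                                    kind="intensive", case=species)
    return out


def gen_region_mask(cfg: SyntheticConfig) -> RegionMask:
    """A synthetic 11-region tiling: longitude bands crossed with latitude
    blocks, labels shuffled by seed.  A stand-in for real country borders —
    exhaustive (no ocean label) so partition sums equal global sums."""
    rng = cfg.rng("mask")
    nlat, nlon = cfg.grid.shape
    n = len(IMF_REGIONS)
    band = np.floor(np.linspace(0, n, nlon, endpoint=False)).astype(int)
    block = np.floor(np.linspace(0, 3, nlat, endpoint=False)).astype(int)
    labels = (band[None, :] + block[:, None] * 5) % n
    perm = rng.permutation(n)
    return RegionMask(cfg.grid, perm[labels], dict(IMF_REGIONS))
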