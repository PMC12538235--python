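"""Hazard-ratio models and attributable burden.

Two exposure-response models drive the burden estimate:

* **GEMM** (Global Exposure Mortality Model) for PM2.5 and the combined
  NCD+LRI endpoint.  With z = max(0, C − C0) and counterfactual
  C0 = 2.4 μg/m³ below which no excess risk is assumed,

      HR(z) = exp( θ · ln(1 + z/α) · ω(z) ),   ω(z) = 1 / (1 + exp(−(z − μ)/ν))

  θ (and its standard error, which carries the 95% CI), α, μ, ν are fit
  constants per 5-year adult age group.

* A **log-linear O3 model** for COPD: HR = exp(η · max(0, Y − 26.7)) with
  Y the annual-mean MDA8 O3 in ppb, slope η = 0.0131 (95% CI
  0.0077–0.0191) and a 26.7 ppb threshold.

Attributable deaths per cell/endpoint/age follow the attributable-fraction
form M = POP × BMR × (HR − 1)/HR, and years of life lost multiply M by the
stratum's mean YLL.  Confidence intervals re-evaluate the full chain at
θ ∓ 1.96·SE (or η at its published bounds); nothing else is perturbed.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .grid import GriddedField, GridSpec, RegionMask
from .synth import ADULT_AGE_GROUPS, PopulationGrid

PM25_COUNTERFACTUAL = 2.4   # μg/m³
O3_THRESHOLD = 26.7         # ppb
CI_MEMBERS = ("low", "central", "high")
Z95 = 1.96


# ---------------------------------------------------------------------------
# parameter sets


# Synthetic default GEMM-shaped parameter table (NCD+LRI, adults).  The
# published age-specific fit values are not redistributed here; this table
# mimics their structure — θ declining with age, a common α/μ/ν shape —
# and is intended for tests and demos.  Real analyses should load the
# published values via ``GEMMParams.from_csv``.
_SYNTHETIC_GEMM_CSV = """endpoint,age,theta,se_theta,alpha,mu,nu
NCD+LRI,25-29,0.1585,0.0149,1.6,15.5,36.8
NCD+LRI,30-34,0.1577,0.0148,1.6,15.5,36.8
NCD+LRI,35-39,0.1570,0.0148,1.6,15.5,36.8
NCD+LRI,40-44,0.1558,0.0147,1.6,15.5,36.8
NCD+LRI,45-49,0.1532,0.0145,1.6,15.5,36.8
NCD+LRI,50-54,0.1499,0.0141,1.6,15.5,36.8
NCD+LRI,55-59,0.1462,0.0138,1.6,15.5,36.8
NCD+LRI,60-64,0.1421,0.0134,1.6,15.5,36.8
NCD+LRI,65-69,0.1374,0.0129,1.6,15.5,36.8
NCD+LRI,70-74,0.1319,0.0124,1.6,15.5,36.8
NCD+LRI,75-79,0.1253,0.0118,1.6,15.5,36.8
NCD+LRI,80+,0.1141,0.0107,1.6,15.5,36.8
"""


@dataclass
class GEMMParams:
    """GEMM fit parameters per (endpoint, age group).

    ``table`` columns: endpoint, age, theta, se_theta, alpha, mu, nu with
    θ > 0, ν > 0; μ, ν in μg/m³, θ, α dimensionless.  CSV schema matches
    the column names exactly.
    """

    table: pd.DataFrame
    c0: float = PM25_COUNTERFACTUAL

    _REQUIRED = ("endpoint", "age", "theta", "se_theta", "alpha", "mu", "nu")

    def __post_init__(self):
        missing = set(self._REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"GEMM table missing columns {sorted(missing)}")
        if (self.table["theta"] <= 0).any() or (self.table["nu"] <= 0).any():
            raise ValueError("theta and nu must be > 0")
        if self.c0 < 0:
            raise ValueError("counterfactual must be >= 0")
        self.table = self.table.set_index(["endpoint", "age"], drop=False) \
            if self.table.index.nlevels == 1 else self.table

    @classmethod
    def synthetic_default(cls) -> "GEMMParams":
        return cls(pd.read_csv(_io.StringIO(_SYNTHETIC_GEMM_CSV)))

    @classmethod
    def from_csv(cls, path) -> "GEMMParams":
        return cls(pd.read_csv(path))

    def row(self, endpoint: str, age: str) -> pd.Series:
        return self.table.loc[(endpoint, age)]

    @property
    def ages(self) -> list[str]:
        return list(self.table["age"].unique())


@dataclass(frozen=True)
class O3Params:
    """Log-linear O3-COPD slope with its 95% CI and exposure threshold."""

    eta: float = 0.0131
    eta_low: float = 0.0077
    eta_high: float = 0.0191
    threshold: float = O3_THRESHOLD

    def __post_init__(self):
        if not (self.eta_low <= self.eta <= self.eta_high):
            raise ValueError("require eta_low <= eta <= eta_high")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")

    def eta_for(self, member: str) -> float:
        return {"low": self.eta_low, "central": self.eta, "high": self.eta_high}[member]


# ---------------------------------------------------------------------------
# hazard ratios


def gemm_hr(conc, theta: float, alpha: float, mu: float, nu: float,
            c0: float = PM25_COUNTERFACTUAL):
    """GEMM hazard ratio at PM2.5 concentration(s) ``conc`` (μg/m³).

    Returns 1 exactly at and below the counterfactual.  Scalar in, scalar
    out; array in, array out.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("PM2.5 concentration must be >= 0")
    z = np.maximum(0.0, c - c0)
    omega = 1.0 / (1.0 + np.exp(-(z - mu) / nu))
    hr = np.exp(theta * np.log1p(z / alpha) * omega)
    return float(hr) if np.isscalar(conc) else hr


def o3_hr(mda8_annual, eta: float, threshold: float = O3_THRESHOLD):
    """O3-COPD hazard ratio at annual-mean MDA8 concentration(s) in ppb."""
    y = np.asarray(mda8_annual, dtype=float)
    if np.any(y < 0):
        raise ValueError("MDA8 O3 concentration must be >= 0")
    hr = np.exp(eta * np.maximum(0.0, y - threshold))
    return float(hr) if np.isscalar(mda8_annual) else hr


def attributable_deaths(pop, bmr, hr):
    """M = POP × BMR × (HR − 1)/HR; the attributable fraction lies in [0, 1)."""
    pop = np.asarray(pop, dtype=float)
    bmr = np.asarray(bmr, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(pop < 0) or np.any(bmr < 0):
        raise ValueError("POP and BMR must be >= 0")
    if np.any(hr < 1):
        raise ValueError("HR must be >= 1")
    return pop * bmr * (hr - 1.0) / hr


def years_of_life_lost(deaths, myll):
    """YLL = M × mean-YLL of the stratum."""
    return np.asarray(deaths, dtype=float) * np.asarray(myll, dtype=float)


# ---------------------------------------------------------------------------
# gridded burden


@dataclass
class BurdenResult:
    """Per-cell, per-age attributable deaths and YLL with CI members.

    ``deaths[member]`` and ``yll[member]`` are (n_age, nlat, nlon) arrays;
    members are low/central/high, ordered low ≤ central ≤ high by the
    monotonicity of HR in θ (or η).
    """

    grid: GridSpec
    endpoint: str
    pollutant: str
    ages: list[str]
    deaths: dict[str, np.ndarray] = dc_field(default_factory=dict)
    yll: dict[str, np.ndarray] = dc_field(default_factory=dict)
    case: str = ""

    def total_deaths(self, member: str = "central") -> float:
        return float(self.deaths[member].sum())

    def total_yll(self, member: str = "central") -> float:
        return float(self.yll[member].sum())

    def deaths_field(self, member: str = "central") -> GriddedField:
        return GriddedField(self.grid, self.deaths[member].sum(axis=0),
                            units="deaths", kind="extensive", case=self.case)

    def yll_grid(self, member: str = "central") -> np.ndarray:
        return self.yll[member].sum(axis=0)

    def totals(self) -> dict[str, float]:
        return {m: self.total_deaths(m) for m in CI_MEMBERS}

    def yll_totals(self) -> dict[str, float]:
        return {m: self.total_yll(m) for m in CI_MEMBERS}


def _expand_regional(table: pd.DataFrame, column: str, mask: RegionMask,
                     endpoint: str, ages: list[str]) -> np.ndarray:
    """(n_age, nlat, nlon) array from a per-(region, endpoint, age) table."""
    sub = table[table["endpoint"] == endpoint].set_index(["region", "age"])[column]
    names = mask.region_names()
    out = np.zeros((len(ages),) + mask.grid.shape)
    for label, name in names.items():
        cells = mask.labels == label
        if not cells.any():
            continue
        for k, age in enumerate(ages):
            out[k][cells] = sub[(name, age)]
    return out


def compute_burden(
    exposure: GriddedField,
    population: PopulationGrid,
    bmr: pd.DataFrame,
    myll: pd.DataFrame,
    mask: RegionMask,
    gemm: GEMMParams | None = None,
    o3: O3Params | None = None,
    pollutant: str = "pm25",
    ages: list[str] | None = None,
) -> BurdenResult:
    """Gridded attributable deaths and YLL with low/central/high members.

    ``pollutant`` selects the model: "pm25" applies GEMM to the NCD+LRI
    endpoint with age-specific θ, "o3" applies the log-linear COPD model.
    BMR and mean-YLL tables are per (region, endpoint, age) and are
    expanded over the mask; population ages are split by the grid's
    age-fraction table.  Only adult (≥ 25) groups contribute.
    """
    if pollutant not in ("pm25", "o3"):
        raise ValueError("pollutant must be 'pm25' or 'o3'")
    if exposure.grid.shape != population.counts.grid.shape:
        raise ValueError("exposure and population must share a grid")
    if mask.grid.shape != exposure.grid.shape:
        raise ValueError("region mask must share the exposure grid")
    ages = list(ages) if ages is not None else list(ADULT_AGE_GROUPS)
    endpoint = "NCD+LRI" if pollutant == "pm25" else "COPD"
    conc = np.maximum(exposure.values, 0.0)  # net fields may dip below zero

    pop_age = np.stack([population.counts_for_age(a) for a in ages])
    bmr_grid = _expand_regional(bmr, "bmr", mask, endpoint, ages)
    myll_grid = _expand_regional(myll, "myll", mask, endpoint, ages)

    result = BurdenResult(exposure.grid, endpoint, pollutant, ages,
                          case=exposure.case)
    for member in CI_MEMBERS:
        if pollutant == "pm25":
            gemm = gemm or GEMMParams.synthetic_default()
            hr = np.empty_like(pop_age)
            for k, age in enumerate(ages):
                p = gemm.row(endpoint, age)
                shift = {"low": -Z95, "central": 0.0, "high": Z95}[member]
                theta = p["theta"] + shift * p["se_theta"]
                hr[k] = gemm_hr(conc, theta, p["alpha"], p["mu"], p["nu"], gemm.c0)
        else:
            o3 = o3 or O3Params()
            hr1 = o3_hr(conc, o3.eta_for(member), o3.threshold)
            hr = np.broadcast_to(hr1, pop_age.shape)
        deaths = attributable_deaths(pop_age, bmr_grid, hr)
        result.deaths[member] = deaths
        result.yll[member] = years_of_life_lost(deaths, myll_grid)
    return result


def net_burden(case_totals: dict[str, float], off_totals: dict[str, float]) -> dict[str, float]:
    """Net-anthropogenic totals: case − OFF per CI member, after totaling.

    May be negative for pathological inputs; reported, never clamped.
    """
    return {m: case_totals[m] - off_totals[m] for m in CI_MEMBERS}


def combine_totals(pm25: dict[str, float], o3: dict[str, float]) -> dict[str, float]:
    """PM2.5 + O3 combined totals; CI bounds are added member-wise (the
    reporting convention for the combined-pollutant row)."""
    return {m: pm25[m] + o3[m] for m in CI_MEMBERS}
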