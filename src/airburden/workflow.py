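"""End-to-end pipeline driver: simulate → exposure → burden → aggregate →
validate → report.

The driver chains every stage on synthetic inputs (or user-supplied
NetCDF/CSV) and writes deterministic CSV summaries; every output is
stamped with the config hash and package version so runs are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import (case_percent_diff, development_ratio, pooled_rates,
                        regional_totals, share_table)
from .exposure import net_concentration
from .grid import GridSpec, area_weighted_mean
from .health import (BurdenResult, GEMMParams, O3Params, combine_totals,
                     compute_burden, net_burden, CI_MEMBERS)
from .synth import (SyntheticConfig, gen_bmr_and_myll, gen_case_pair,
                    gen_population, gen_region_mask, gen_stations)
from .validate import match_stations, nmb, pearson_r

log = logging.getLogger(__name__)

_CONFIG_KEYS = {
    "seed", "cases", "baseline", "anthropogenic_shares", "grid_nlat",
    "grid_nlon", "mda8_convention", "out_dir", "population_total",
    "background_median", "background_sigma_log", "n_hotspots",
    "hotspot_amplitude", "station_count", "obs_noise_cv", "urban_fraction",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (strict: unknown keys refuse)."""

    seed: int = 0
    cases: dict[str, float] = dc_field(
        default_factory=lambda: {"CEDS": 0.50, "CAMS": 0.55, "ECLIPSE": 0.40}
    )
    baseline: str = "CEDS"
    grid_nlat: int = 36
    grid_nlon: int = 72
    mda8_convention: str = "sameday"
    out_dir: str = "out"
    population_total: float = 7.3e9
    background_median: float = 10.0
    background_sigma_log: float = 0.5
    n_hotspots: int = 8
    hotspot_amplitude: float = 30.0
    station_count: int = 100
    obs_noise_cv: float = 0.10
    urban_fraction: float = 0.54

    def __post_init__(self):
        if self.baseline not in self.cases:
            raise ValueError(f"baseline {self.baseline!r} must be one of the cases "
                             f"{list(self.cases)}")
        if self.mda8_convention not in ("sameday", "epa"):
            raise ValueError("mda8_convention must be 'sameday' or 'epa'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        shares = raw.pop("anthropogenic_shares", None)
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if shares is not None:
            raw["cases"] = {str(k): float(v) for k, v in shares.items()}
        return cls(**raw)

    def config_hash(self) -> str:
        # hash the scientific configuration only: where outputs land must
        # not change what they contain
        d = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def synth_config(self) -> SyntheticConfig:
        dlat, dlon = 180.0 / self.grid_nlat, 360.0 / self.grid_nlon
        return SyntheticConfig(
            seed=self.seed,
            grid=GridSpec.global_grid(dlat, dlon),
            n_hotspots=self.n_hotspots,
            background_median=self.background_median,
            background_sigma_log=self.background_sigma_log,
            hotspot_amplitude=self.hotspot_amplitude,
            population_total=self.population_total,
            urban_fraction=self.urban_fraction,
            station_count=self.station_count,
            obs_noise_cv=self.obs_noise_cv,
        )


def _write_csv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# airburden {__version__} config={stamp}\n")
        df.to_csv(fh, float_format="%.6f")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic-data pipeline and write summary CSVs.

    Per case: a PM2.5 and an O3 concentration field plus the matching
    zero-anthropogenic (OFF) fields are generated; net burdens are the
    difference of case and OFF totals per CI member.  Outputs land in
    ``config.out_dir``: one regional summary CSV per case, a cross-case
    comparison, pooled developed/developing rates, and validation stats.
    Deterministic given (config, seed) — identical bytes on reruns.
    """
    out = Path(config.out_dir)
    stamp = config.config_hash()
    if not config.cases:
        raise ValueError("at least one emission case is required")

    cfg0 = config.synth_config()
    log.info("simulate: grid %s, %d cases", cfg0.grid.shape, len(config.cases))
    population = gen_population(cfg0)
    bmr, myll = gen_bmr_and_myll(cfg0)
    mask = gen_region_mask(cfg0)
    gemm = GEMMParams.synthetic_default()
    o3p = O3Params()

    summaries: dict[str, pd.DataFrame] = {}
    validation_rows = []
    results: dict[str, dict] = {}
    for idx, (case, share) in enumerate(sorted(config.cases.items())):
        # per-case seed offset so cases differ but stay reproducible
        c = config.synth_config()
        c.seed = config.seed * 1000 + idx
        pm_case, pm_off = gen_case_pair(c, share, units="ug/m3", case=case)
        c_o3 = config.synth_config()
        c_o3.seed = config.seed * 1000 + 500 + idx
        c_o3.background_median = 35.0
        c_o3.hotspot_amplitude = 20.0
        o3_case, o3_off = gen_case_pair(c_o3, share, units="ppbv", case=case)

        burdens: dict[str, BurdenResult] = {}
        net = {}
        for pol, (f_case, f_off) in (("pm25", (pm_case, pm_off)),
                                     ("o3", (o3_case, o3_off))):
            b_case = compute_burden(f_case, population, bmr, myll, mask,
                                    gemm=gemm, o3=o3p, pollutant=pol)
            b_off = compute_burden(f_off, population, bmr, myll, mask,
                                   gemm=gemm, o3=o3p, pollutant=pol)
            burdens[pol] = b_case
            net[pol] = {
                "deaths": net_burden(b_case.totals(), b_off.totals()),
                "yll": net_burden(b_case.yll_totals(), b_off.yll_totals()),
            }
        net["combined"] = {
            "deaths": combine_totals(net["pm25"]["deaths"], net["o3"]["deaths"]),
            "yll": combine_totals(net["pm25"]["yll"], net["o3"]["yll"]),
        }

        # regional reporting uses the case burden (gridded); net reporting
        # is at the totals level, as the workflow prescribes
        summary_pm = regional_totals(burdens["pm25"], mask, population)
        summary_o3 = regional_totals(burdens["o3"], mask, population)
        combined = summary_pm.copy()
        for m in CI_MEMBERS:
            combined[f"deaths_{m}"] += summary_o3[f"deaths_{m}"]
            combined[f"yll_{m}"] += summary_o3[f"yll_{m}"]
            combined[f"rate_{m}"] = (combined[f"deaths_{m}"]
                                     / combined["population"] * 1e5)
        total = combined.loc["Global", "deaths_central"]
        combined["share_pct"] = combined["deaths_central"] / total * 100.0
        summaries[case] = combined
        _write_csv(combined.round(6), out / f"summary_{case}.csv", stamp)
        _write_csv(pooled_rates(combined.drop(index="Global")).round(6),
                   out / f"pooled_rates_{case}.csv", stamp)

        stations = gen_stations(c, pm_case)
        pairs = match_stations(stations, pm_case)
        validation_rows.append({
            "case": case,
            "n_stations": len(pairs),
            "nmb_pct": nmb(pairs),
            "pearson_r": pearson_r(pairs),
        })
        results[case] = {
            "net": net,
            "net_pm25_mean": area_weighted_mean(net_concentration(pm_case, pm_off)),
            "net_o3_mean": area_weighted_mean(net_concentration(o3_case, o3_off)),
            "dev_ratio": development_ratio(combined.drop(index="Global")),
            "share": share_table(combined),
        }
        log.info("case %s: net combined deaths %.1f", case,
                 net["combined"]["deaths"]["central"])

    base = config.baseline
    diffs = {c: case_percent_diff(summaries[c], summaries[base])
             for c in summaries if c != base}
    if diffs:
        _write_csv(pd.DataFrame(diffs).round(6), out / "case_percent_diff.csv", stamp)
    _write_csv(pd.DataFrame(validation_rows).set_index("case").round(6),
               out / "validation.csv", stamp)

    net_rows = []
    for case, r in sorted(results.items()):
        for pol in ("pm25", "o3", "combined"):
            row = {"case": case, "pollutant": pol}
            row.update({f"deaths_{m}": r["net"][pol]["deaths"][m] for m in CI_MEMBERS})
            row.update({f"yll_{m}": r["net"][pol]["yll"][m] for m in CI_MEMBERS})
            net_rows.append(row)
    _write_csv(pd.DataFrame(net_rows).set_index(["case", "pollutant"]).round(3),
               out / "net_burden.csv", stamp)
    return {"summaries": summaries, "results": results,
            "validation": pd.DataFrame(validation_rows).set_index("case"),
            "stamp": stamp}
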