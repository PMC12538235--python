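"""Regional and global summaries of the gridded burden.

Cell-exhaustive partition sums over the 11-region mask, per-capita rates
per 100,000, the pooled developed-vs-developing comparison, percent shares
of the global total, and case-vs-baseline percentage differences.
Cells whose label is absent from the registry are reported under an
explicit "unassigned" row — counted in the global total, never dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import RegionMask
from .health import CI_MEMBERS, BurdenResult
from .synth import PopulationGrid

#: Figure-style continental grouping used for the Asia+Africa share
ASIA_AFRICA = ("China", "India", "ROA", "NAME", "SSA")


def regional_totals(burden: BurdenResult, mask: RegionMask,
                    population: PopulationGrid) -> pd.DataFrame:
    """Per-region deaths/YLL (low, central, high), population, APD rate per
    100,000 and share of the global total.  A "Global" row closes the
    table; Σ regional deaths equals the global sum exactly (partition)."""
    rows = {}
    labels = mask.labels
    names = mask.region_names()
    uniq = np.unique(labels)
    deaths_grid = {m: burden.deaths[m].sum(axis=0) for m in CI_MEMBERS}
    yll_grid = {m: burden.yll[m].sum(axis=0) for m in CI_MEMBERS}
    pop = population.counts.values

    for label in uniq:
        cells = labels == label
        name = names.get(label, "unassigned")
        status = mask.registry.get(label, (None, "unassigned"))[1]
        row = {"status": status, "population": float(pop[cells].sum())}
        for m in CI_MEMBERS:
            row[f"deaths_{m}"] = float(deaths_grid[m][cells].sum())
            row[f"yll_{m}"] = float(yll_grid[m][cells].sum())
        if name in rows:  # two labels mapping to one name pool together
            for k, v in row.items():
                if k != "status":
                    rows[name][k] += v
        else:
            rows[name] = row

    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("region")
    glob = {"status": "global", "population": df["population"].sum()}
    for m in CI_MEMBERS:
        glob[f"deaths_{m}"] = df[f"deaths_{m}"].sum()
        glob[f"yll_{m}"] = df[f"yll_{m}"].sum()
    df.loc["Global"] = glob
    for m in CI_MEMBERS:
        df[f"rate_{m}"] = apd_rate(df[f"deaths_{m}"], df["population"])
    total = df.loc["Global", "deaths_central"]
    df["share_pct"] = np.where(total > 0, df["deaths_central"] / total * 100.0, 0.0)
    return df


def apd_rate(deaths, population):
    """Premature-death rate per 100,000 population."""
    deaths = np.asarray(deaths, dtype=float)
    population = np.asarray(population, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = deaths / population * 1e5
    return np.where(population > 0, r, 0.0)


def development_ratio(summary: pd.DataFrame, member: str = "central") -> float:
    """Pooled developing-to-developed APD-rate ratio.

    Pooled rate = Σ deaths / Σ population within each status group; the
    ratio compares the two pooled rates (not an average of region rates).
    """
    rates = {}
    for status in ("developing", "developed"):
        sub = summary[summary["status"] == status]
        if sub.empty or sub["population"].sum() <= 0:
            raise ValueError(f"no {status} population in summary")
        rates[status] = sub[f"deaths_{member}"].sum() / sub["population"].sum()
    if rates["developed"] == 0:
        raise ValueError("developed pooled rate is zero")
    return float(rates["developing"] / rates["developed"])


def pooled_rates(summary: pd.DataFrame) -> pd.DataFrame:
    """Developed/developing pooled APD rates per 100,000 with CI members."""
    rows = []
    for status in ("developed", "developing"):
        sub = summary[summary["status"] == status]
        pop = sub["population"].sum()
        row = {"status": status, "population": pop}
        for m in CI_MEMBERS:
            row[f"rate_{m}"] = float(apd_rate(sub[f"deaths_{m}"].sum(), pop))
        rows.append(row)
    return pd.DataFrame(rows).set_index("status")


def share_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Percent of global deaths per region plus the Asia+Africa grouping."""
    regions = summary.drop(index="Global", errors="ignore")
    total = regions["deaths_central"].sum()
    shares = regions["deaths_central"] / total * 100.0
    out = shares.to_frame("share_pct")
    aa = [r for r in ASIA_AFRICA if r in out.index]
    out.loc["Asia+Africa"] = out.loc[aa, "share_pct"].sum()
    return out


def case_percent_diff(summary_case: pd.DataFrame, summary_baseline: pd.DataFrame,
                      column: str = "deaths_central") -> pd.Series:
    """Per-region percent difference of a case against the baseline case."""
    base = summary_baseline[column]
    if (base <= 0).any():
        raise ValueError("baseline totals must be > 0 in every region")
    return ((summary_case[column] - base) / base * 100.0).rename("pct_diff")


def gbd_share(case_total: float, gbd_total: float) -> float:
    """A case's attributable deaths as a percent of the all-cause
    (NCD+LRI) death count of the reference burden study."""
    if gbd_total <= 0:
        raise ValueError("reference total must be > 0")
    if case_total < 0:
        raise ValueError("case total must be >= 0")
    return case_total / gbd_total * 100.0
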