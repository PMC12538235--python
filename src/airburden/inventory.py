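"""Global annual emission totals per species and inventory-comparison
arithmetic.

Totals are reported in Tg of species per year; NOx archived as NO is
converted to NO2-equivalent mass before comparison.  Percent differences
against a named baseline inventory and per-species shares of the total are
computed from unrounded totals and then rounded (totals to 0.1 Tg,
percentages to the nearest integer), so published comparison figures
reproduce deterministically.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GriddedField, cell_areas

SPECIES = ("BC", "OC", "NO2", "CO", "NMVOC", "NH3", "SO2")

MOLAR_MASS_NO = 30.0061   # g/mol
MOLAR_MASS_NO2 = 46.0055  # g/mol


@dataclass(frozen=True)
class SpeciesTotal:
    species: str
    inventory: str
    total_tg: float

    def __post_init__(self):
        if self.total_tg < 0:
            raise ValueError("total must be >= 0")


def seconds_in_year(year: int) -> float:
    return (366 if calendar.isleap(year) else 365) * 86400.0


def global_total(flux: GriddedField, year: int) -> float:
    """Area-integrate an emission-flux field to Tg/yr.

    Σ(flux × cell area × seconds in the calendar year) × 1e-9.
    """
    if flux.units != "kg m-2 s-1":
        raise ValueError(f"flux field must carry units 'kg m-2 s-1', got {flux.units!r}")
    areas = cell_areas(flux.grid).values
    kg = float(np.nansum(flux.values * areas)) * seconds_in_year(year)
    return kg * 1e-9


def no_to_no2(mass_no_tg: float) -> float:
    """Convert a mass of NO to the NO2-equivalent mass (same moles)."""
    if mass_no_tg < 0:
        raise ValueError("mass must be >= 0")
    return mass_no_tg * (MOLAR_MASS_NO2 / MOLAR_MASS_NO)


def percent_diff(value: float, baseline: float) -> float:
    """(value − baseline)/baseline × 100."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return (value - baseline) / baseline * 100.0


def species_share(species_total: float, all_species_totals: dict[str, float] | pd.Series) -> float:
    """One species' percent share of the summed totals of an inventory."""
    denom = float(pd.Series(all_species_totals).sum())
    if denom <= 0:
        raise ValueError("inventory totals must sum to > 0")
    return species_total / denom * 100.0


def nmvoc_total(component_totals: dict[str, float] | pd.Series) -> float:
    """NMVOC as the sum of its individually-totaled component species."""
    s = pd.Series(component_totals, dtype=float)
    if (s < 0).any():
        raise ValueError("component totals must be >= 0")
    return float(s.sum())


def comparison_table(inventories: dict[str, dict[str, float]],
                     baseline: str | None = None) -> pd.DataFrame:
    """Long-format comparison of per-species totals across inventories.

    ``inventories`` maps inventory label -> {species: Tg/yr}.  Rows are
    ordered by the canonical species order then inventory label; percent
    differences use unrounded totals and round to integer, totals round to
    0.1 Tg.  An empty input yields an empty table.
    """
    if not inventories:
        return pd.DataFrame(columns=["species", "inventory", "total_tg", "pct_diff_vs_baseline"])
    if baseline is not None and baseline not in inventories:
        raise ValueError(f"baseline {baseline!r} not among inventories")
    rows = []
    labels = list(inventories)
    all_species = [s for s in SPECIES if any(s in inv for inv in inventories.values())]
    extra = sorted({s for inv in inventories.values() for s in inv} - set(all_species))
    for species in all_species + extra:
        for label in labels:
            if species not in inventories[label]:
                continue
            total = inventories[label][species]
            if baseline is not None and species in inventories[baseline]:
                pct = round(percent_diff(total, inventories[baseline][species])) \
                    if inventories[baseline][species] > 0 else np.nan
            else:
                pct = np.nan
            rows.append((species, label, round(total, 1), pct))
    return pd.DataFrame(rows, columns=["species", "inventory", "total_tg",
                                       "pct_diff_vs_baseline"])
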