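"""Model-vs-observation statistics: station matching, normalized mean
bias, Pearson correlation, and gridded mean bias on a coarse comparison
grid."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GriddedField, cell_areas, regrid

log = logging.getLogger(__name__)


def match_stations(stations: pd.DataFrame, field: GriddedField,
                   average_per_cell: bool = False) -> pd.DataFrame:
    """Pair each station with the value of the grid cell containing it.

    Cells are half-open on their upper bound, so a station sitting exactly
    on an interior edge is assigned deterministically to the cell above.
    Stations outside the grid are dropped (count logged).  With
    ``average_per_cell`` stations sharing a cell are first averaged into a
    single pair; default keeps one pair per station.
    """
    latb, lonb = field.grid.lat_bounds, field.grid.lon_bounds
    lat = stations["lat"].to_numpy(float)
    lon = stations["lon"].to_numpy(float)
    inside = (lat >= latb[0]) & (lat < latb[-1]) & (lon >= lonb[0]) & (lon < lonb[-1])
    # stations exactly on the outer upper bound still belong to the last cell
    inside |= np.isclose(lat, latb[-1]) & (lon >= lonb[0]) & (lon < lonb[-1])
    dropped = int((~inside).sum())
    if dropped:
        log.info("match_stations: dropped %d stations outside the grid", dropped)
    sub = stations[inside].copy()
    ii = np.clip(np.searchsorted(latb, sub["lat"].to_numpy(float), side="right") - 1,
                 0, field.grid.shape[0] - 1)
    jj = np.clip(np.searchsorted(lonb, sub["lon"].to_numpy(float), side="right") - 1,
                 0, field.grid.shape[1] - 1)
    sub["model"] = field.values[ii, jj]
    sub = sub.rename(columns={"value": "obs"})
    sub = sub[np.isfinite(sub["obs"]) & np.isfinite(sub["model"])]
    if average_per_cell:
        sub["_cell"] = ii * field.grid.shape[1] + jj
        agg = {c: "mean" for c in ("lat", "lon", "obs", "model")}
        sub = sub.groupby("_cell", as_index=False).agg(agg)
    return sub.reset_index(drop=True)


def nmb(pairs: pd.DataFrame) -> float:
    """Normalized mean bias in percent: Σ(model − obs) / Σ obs × 100."""
    obs = pairs["obs"].to_numpy(float)
    model = pairs["model"].to_numpy(float)
    denom = obs.sum()
    if denom <= 0:
        raise ValueError("sum of observations must be > 0")
    return float((model - obs).sum() / denom * 100.0)


def pearson_r(pairs: pd.DataFrame) -> float:
    """Pearson correlation between matched model and observed values."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs for a correlation")
    return float(stats.pearsonr(pairs["obs"], pairs["model"]).statistic)


def gridded_mean_bias(model: GriddedField, obs: GriddedField,
                      area_weighted: bool = False) -> tuple[GriddedField, float]:
    """Bias field (model − obs) on the observation grid plus its scalar
    mean over cells where observations exist.

    The model is regridded bilinearly to the (coarser) obs grid; cells
    without observations stay missing.  The scalar is an unweighted mean
    over valid cells by default; ``area_weighted`` switches to
    area-weighting.
    """
    on_obs = regrid(model, obs.grid, method="bilinear")
    valid = np.isfinite(obs.values)
    bias = np.where(valid, on_obs.values - obs.values, np.nan)
    if not valid.any():
        raise ValueError("no overlapping observations")
    if area_weighted:
        w = cell_areas(obs.grid).values[valid]
        scalar = float(np.sum(bias[valid] * w) / w.sum())
    else:
        scalar = float(np.mean(bias[valid]))
    bias_field = GriddedField(obs.grid, bias, units=model.units,
                              kind="intensive", case=model.case, difference=True)
    return bias_field, scalar
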