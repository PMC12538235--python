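"""Exposure fields for the health-impact stage.

Three preparations feed the burden calculation: the annual-mean MDA8 ozone
metric computed from hourly series, satellite-anchored multiplicative
downscaling of coarse model PM2.5 to the 0.1° analysis grid, and the
net-anthropogenic concentration difference between an emission case and
the zero-anthropogenic baseline run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GriddedField, GridSpec, regrid

#: calibration factors are clipped to this range to keep the adjustment
#: multiplicative and bounded where the model goes to zero
FACTOR_BOUNDS = (0.1, 10.0)

#: a day needs at least this many valid hours to yield an MDA8 value
MIN_VALID_HOURS = 18

#: a running window needs at least this many of its 8 hours
MIN_WINDOW_HOURS = 6


def mda8(hourly: np.ndarray, convention: str = "sameday") -> tuple[np.ndarray, float]:
    """Daily MDA8 series and the annual mean over valid days.

    ``hourly`` is (days, 24) or flat with length a multiple of 24; NaN
    marks missing hours.  Per day the MDA8 is the maximum over running
    8-hour means; under ``sameday`` the 17 windows starting at hours 0–16
    are used, under ``epa`` all 24 start hours, the last seven extending
    into the next day.  A day with fewer than 18 valid hours yields NaN;
    a window needs ≥ 6 of its 8 hours.
    """
    if convention not in ("sameday", "epa"):
        raise ValueError(f"unknown MDA8 convention {convention!r}")
    h = np.asarray(hourly, dtype=float)
    if h.ndim == 1:
        if h.size % 24:
            raise ValueError("flat hourly series length must be a multiple of 24")
        h = h.reshape(-1, 24)
    if h.ndim != 2 or h.shape[1] != 24 or h.shape[0] < 1:
        raise ValueError("hourly must be (days, 24) with >=1 day")

    flat = h.ravel()
    n_days = h.shape[0]
    starts_per_day = 17 if convention == "sameday" else 24
    out = np.full(n_days, np.nan)
    valid_hours = np.sum(np.isfinite(h), axis=1)
    for d in range(n_days):
        if valid_hours[d] < MIN_VALID_HOURS:
            continue
        best = -np.inf
        for s in range(starts_per_day):
            i0 = d * 24 + s
            w = flat[i0:i0 + 8]
            if w.size < 8:       # epa windows running past the series end
                continue
            good = np.isfinite(w)
            if good.sum() < MIN_WINDOW_HOURS:
                continue
            best = max(best, float(np.mean(w[good])))
        if np.isfinite(best):
            out[d] = best
    annual = float(np.nanmean(out)) if np.any(np.isfinite(out)) else np.nan
    return out, annual


@dataclass
class CalibrationMap:
    """Per-cell multiplicative PM2.5 adjustment on the analysis grid.

    ``factor`` is satellite / regridded-model clipped to [0.1, 10];
    ``valid`` is False where the satellite reference is missing (there the
    factor is 1 and the model passes through unadjusted).
    """

    grid: GridSpec
    factor: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.factor = np.asarray(self.factor, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.factor.shape != self.grid.shape or self.valid.shape != self.grid.shape:
            raise ValueError("factor/valid shape must match grid")
        lo, hi = FACTOR_BOUNDS
        if np.any((self.factor < lo) | (self.factor > hi)):
            raise ValueError(f"factors must lie within [{lo}, {hi}]")
        if np.any(self.factor[~self.valid] != 1.0):
            raise ValueError("factor must be 1 where the reference is missing")


def calibration_map(model_on_target: GriddedField, satellite: GriddedField) -> CalibrationMap:
    valid = np.isfinite(satellite.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = satellite.values / model_on_target.values
    lo, hi = FACTOR_BOUNDS
    factor = np.where(valid, np.clip(np.nan_to_num(raw, nan=1.0, posinf=hi), lo, hi), 1.0)
    return CalibrationMap(satellite.grid, factor, valid)


def downscale_pm25(model: GriddedField, satellite: GriddedField) -> GriddedField:
    """Satellite-anchored downscaling of a coarse PM2.5 field.

    The model is regridded bilinearly to the satellite's (finer) grid and
    multiplied cellwise by the clipped satellite/model ratio; where the
    satellite reference is missing the regridded model is returned as-is.
    If the satellite field is itself a bilinear upsampling of the model,
    the output recovers the satellite exactly.
    """
    if np.nanmin(model.values) < 0 or np.nanmin(satellite.values) < 0:
        raise ValueError("concentration fields must be non-negative")
    fine = regrid(model, satellite.grid, method="bilinear")
    cal = calibration_map(fine, satellite)
    vals = fine.values * cal.factor
    return GriddedField(satellite.grid, vals, units=model.units,
                        kind="intensive", case=model.case)


def net_concentration(case: GriddedField, off: GriddedField) -> GriddedField:
    """Cellwise case − OFF concentration difference (net anthropogenic
    contribution).  May be negative; antisymmetric in its arguments."""
    if case.grid.shape != off.grid.shape or not np.allclose(case.grid.lat, off.grid.lat):
        raise ValueError("case and OFF fields must share a grid")
    if case.units != off.units:
        raise ValueError("case and OFF fields must share units")
    return GriddedField(case.grid, case.values - off.values, units=case.units,
                        kind="intensive", case=case.case, difference=True)
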