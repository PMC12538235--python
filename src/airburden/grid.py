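"""Regular lat-lon grid data model, spherical cell areas, and regridding.

The analysis moves fields between three resolutions (a coarse model grid
near 1°, a 0.1° analysis grid, and a 2° comparison grid).  Intensive
quantities (concentrations) are interpolated; extensive quantities
(population counts, emission mass, deaths) are remapped conservatively so
their global integrals survive every resolution change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.interpolate import RegularGridInterpolator

EARTH_RADIUS_M = 6.371e6

#: units whose fields must be non-negative (physical stocks/concentrations)
_NONNEG_UNITS = {"ug/m3", "ppbv", "persons", "kg m-2 s-1", "deaths", "m2"}


@dataclass(frozen=True)
class GridSpec:
    """A regular cell-centered latitude-longitude grid.

    Latitude centers are strictly increasing in [-90, 90]; longitude
    centers strictly increasing in [-180, 180).  Cell bounds run midpoint
    to midpoint, extended by half a spacing at the edges (latitude bounds
    clipped to the poles); cells are half-open on their upper edge.
    """

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self):
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        for name, c in (("lat", lat), ("lon", lon)):
            if c.ndim != 1 or c.size < 2:
                raise ValueError(f"{name} centers must be 1-D with >=2 cells")
            d = np.diff(c)
            if np.any(d <= 0):
                raise ValueError(f"{name} centers must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
                raise ValueError(f"{name} spacing must be uniform")
        if lat[0] < -90 or lat[-1] > 90:
            raise ValueError("latitude centers must lie in [-90, 90]")
        if lon[0] < -180 or lon[-1] >= 180:
            raise ValueError("longitude centers must lie in [-180, 180)")

    # -- derived geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    @property
    def dlat(self) -> float:
        return float(self.lat[1] - self.lat[0])

    @property
    def dlon(self) -> float:
        return float(self.lon[1] - self.lon[0])

    @property
    def lat_bounds(self) -> np.ndarray:
        """Midpoint-to-midpoint latitude bounds, clipped to the poles."""
        b = np.concatenate(
            [[self.lat[0] - self.dlat / 2],
             (self.lat[:-1] + self.lat[1:]) / 2,
             [self.lat[-1] + self.dlat / 2]]
        )
        return np.clip(b, -90.0, 90.0)

    @property
    def lon_bounds(self) -> np.ndarray:
        return np.concatenate(
            [[self.lon[0] - self.dlon / 2],
             (self.lon[:-1] + self.lon[1:]) / 2,
             [self.lon[-1] + self.dlon / 2]]
        )

    @classmethod
    def global_grid(cls, dlat: float, dlon: float) -> "GridSpec":
        """A global grid with the given spacings, centers offset half a cell
        from the poles/dateline (e.g. global_grid(1, 1) has centers at
        -89.5 ... 89.5 and -179.5 ... 179.5)."""
        lat = np.arange(-90 + dlat / 2, 90, dlat)
        lon = np.arange(-180 + dlon / 2, 180, dlon)
        return cls(lat, lon)

    def is_global(self) -> bool:
        lb, gb = self.lat_bounds, self.lon_bounds
        return (
            abs(lb[0] + 90) < 1e-9
            and abs(lb[-1] - 90) < 1e-9
            and abs((gb[-1] - gb[0]) - 360) < 1e-9
        )


@dataclass
class GriddedField:
    """Values on a :class:`GridSpec` with units, kind and case metadata.

    ``kind`` is "intensive" (per-area or per-volume quantity: μg/m³, ppbv,
    flux) or "extensive" (a per-cell stock: persons, deaths, m²).  Fields
    carrying physical concentrations or counts must be non-negative;
    difference fields (``difference=True``) may go negative.
    """

    grid: GridSpec
    values: np.ndarray
    units: str
    kind: str = "intensive"
    case: str = ""
    difference: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not self.units:
            raise ValueError("a units tag is required")
        if self.kind not in ("intensive", "extensive"):
            raise ValueError("kind must be 'intensive' or 'extensive'")
        if (
            not self.difference
            and self.units in _NONNEG_UNITS
            and np.nanmin(self.values) < 0
        ):
            raise ValueError(f"{self.units} field must be non-negative")

    def with_values(self, values: np.ndarray, **kw) -> "GriddedField":
        out = replace(self, values=values)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class RegionMask:
    """Integer region labels on a grid plus a label registry.

    ``registry`` maps label -> (region name, development status).  Label -1
    marks ocean/unassigned cells.
    """

    grid: GridSpec
    labels: np.ndarray
    registry: Mapping[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape must match grid")
        used = set(np.unique(self.labels)) - {-1}
        missing = used - set(self.registry)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from registry")
        for lbl, (name, status) in self.registry.items():
            if status not in ("developed", "developing"):
                raise ValueError(f"bad status {status!r} for region {name}")

    def region_names(self) -> dict[int, str]:
        return {k: v[0] for k, v in self.registry.items()}


#: The 11-region global partition used for regional burden reporting, with
#: the developed/developing assignment used for the per-capita comparison.
IMF_REGIONS: dict[int, tuple[str, str]] = {
    0: ("China", "developing"),
    1: ("India", "developing"),
    2: ("USA", "developed"),
    3: ("Canada", "developed"),
    4: ("ECEUROPE", "developing"),
    5: ("WEUROPE", "developed"),
    6: ("LATIN", "developing"),
    7: ("NAME", "developing"),
    8: ("ROA", "developing"),
    9: ("SSA", "developing"),
    10: ("ROW", "developed"),
}


# ---------------------------------------------------------------------------
# areas


def cell_areas(grid: GridSpec, radius: float = EARTH_RADIUS_M) -> GriddedField:
    """Spherical cell areas in m² as an extensive field.

    A = R² Δλ (sin φ_top − sin φ_bot); over a global grid the areas sum to
    4πR² to machine precision.
    """
    latb = np.deg2rad(grid.lat_bounds)
    lonb = np.deg2rad(grid.lon_bounds)
    band = radius**2 * np.diff(np.sin(latb))  # per-latitude strip, unit Δλ
    areas = np.outer(band, np.diff(lonb))
    return GriddedField(grid, areas, units="m2", kind="extensive")


def area_weighted_mean(f: GriddedField) -> float:
    """Global area-weighted mean of an intensive field (NaN-aware)."""
    w = cell_areas(f.grid).values
    m = np.isfinite(f.values)
    return float(np.sum(f.values[m] * w[m]) / np.sum(w[m]))


def global_integral(f: GriddedField) -> float:
    """Sum of an extensive field, or area-integral of an intensive one."""
    if f.kind == "extensive":
        return float(np.nansum(f.values))
    return float(np.nansum(f.values * cell_areas(f.grid).values))


# ---------------------------------------------------------------------------
# regridding


def _interval_overlap(src_b: np.ndarray, tgt_b: np.ndarray,
                      circular: bool = False) -> np.ndarray:
    """Pairwise overlap lengths between two sets of 1-D intervals.

    ``src_b``/``tgt_b`` are bound vectors (n+1 for n cells).  With
    ``circular`` the overlap is evaluated at shifts of ±360° as well, so
    cells straddling the antimeridian are matched after unwrapping.
    """
    s_lo, s_hi = src_b[:-1, None], src_b[1:, None]
    shifts = (-360.0, 0.0, 360.0) if circular else (0.0,)
    out = np.zeros((src_b.size - 1, tgt_b.size - 1))
    for k in shifts:
        t_lo, t_hi = tgt_b[None, :-1] + k, tgt_b[None, 1:] + k
        out += np.clip(np.minimum(s_hi, t_hi) - np.maximum(s_lo, t_lo), 0, None)
    return out


def _conservative(field: GriddedField, target: GridSpec) -> np.ndarray:
    """Overlap-area-weighted remapping.

    Extensive fields: each source cell's stock is split among target cells
    in proportion to fractional area overlap (integral preserved exactly).
    Intensive fields: target values are overlap-area-weighted means.
    """
    src = field.grid
    # fractional overlaps in sin(lat) space give true spherical areas
    sin_s = np.sin(np.deg2rad(src.lat_bounds))
    sin_t = np.sin(np.deg2rad(target.lat_bounds))
    w_lat = _interval_overlap(sin_s, sin_t)                       # (ns, nt)
    w_lon = _interval_overlap(src.lon_bounds, target.lon_bounds, circular=True)
    if w_lat.sum() == 0 or w_lon.sum() == 0:
        raise ValueError("source and target grids do not overlap")
    v = np.nan_to_num(field.values)
    if field.kind == "extensive":
        # normalize rows: fraction of each source cell going to each target
        f_lat = w_lat / np.maximum(w_lat.sum(axis=1, keepdims=True), 1e-300)
        f_lon = w_lon / np.maximum(w_lon.sum(axis=1, keepdims=True), 1e-300)
        return f_lat.T @ v @ f_lon
    num = w_lat.T @ v @ w_lon
    den = np.outer(w_lat.sum(axis=0), w_lon.sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 0, out, np.nan)


def _point_interp(field: GriddedField, target: GridSpec, method: str) -> np.ndarray:
    src = field.grid
    # refuse disjoint grids (cell-bound bounding boxes that never touch)
    if (
        src.lat_bounds[-1] < target.lat_bounds[0]
        or target.lat_bounds[-1] < src.lat_bounds[0]
    ):
        raise ValueError("source and target grids do not overlap")
    interp = RegularGridInterpolator(
        (src.lat, src.lon), field.values, method=method,
        bounds_error=False, fill_value=None,
    )
    # clamp target centers into the source center range: edge cells take the
    # nearest source value instead of extrapolating outside the data
    tlat = np.clip(target.lat, src.lat[0], src.lat[-1])
    tlon = np.clip(target.lon, src.lon[0], src.lon[-1])
    pts_lat, pts_lon = np.meshgrid(tlat, tlon, indexing="ij")
    return interp(np.stack([pts_lat.ravel(), pts_lon.ravel()], axis=1)).reshape(
        target.shape
    )


def regrid(field: GriddedField, target: GridSpec, method: str = "bilinear") -> GriddedField:
    """Remap a field to ``target`` by ``conservative``, ``bilinear`` or
    ``nearest``.

    Extensive fields require the conservative method (anything else would
    silently destroy their integral).  Bilinear and nearest outputs are
    bounded by the source min/max.
    """
    if method not in ("conservative", "bilinear", "nearest"):
        raise ValueError(f"unknown regrid method {method!r}")
    if field.kind == "extensive" and method != "conservative":
        raise ValueError(
            "extensive fields must be regridded conservatively to preserve totals"
        )
    if method == "conservative":
        vals = _conservative(field, target)
    else:
        vals = _point_interp(field, target, {"bilinear": "linear", "nearest": "nearest"}[method])
    return GriddedField(
        target, vals, units=field.units, kind=field.kind,
        case=field.case, difference=field.difference,
    )


def coarsen_mean(field: GriddedField, factor: int) -> GriddedField:
    """Block-aggregate by an integer factor: area-weighted mean for
    intensive fields, block sum for extensive ones.  Dimensions must divide
    by ``factor``; factor 1 is the identity."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nlat, nlon = field.grid.shape
    if nlat % factor or nlon % factor:
        raise ValueError(f"grid {field.grid.shape} not divisible by factor {factor}")
    if factor == 1:
        return field.with_values(field.values.copy())
    new = GridSpec(
        field.grid.lat.reshape(-1, factor).mean(axis=1),
        field.grid.lon.reshape(-1, factor).mean(axis=1),
    )
    blocks = field.values.reshape(nlat // factor, factor, nlon // factor, factor)
    if field.kind == "extensive":
        vals = blocks.sum(axis=(1, 3))
    else:
        w = cell_areas(field.grid).values.reshape(blocks.shape)
        vals = (blocks * w).sum(axis=(1, 3)) / w.sum(axis=(1, 3))
    return GriddedField(
        new, vals, units=field.units, kind=field.kind,
        case=field.case, difference=field.difference,
    )
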