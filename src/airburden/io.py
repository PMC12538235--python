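"""NetCDF and CSV round-tripping for gridded fields and tables.

Fields are written as CF-style NetCDF (classic format via the scipy
backend) with lat/lon coordinate variables and ``units``/``kind``/``case``
attributes, so any CF-aware tool can read them back.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import xarray as xr

from .grid import GriddedField, GridSpec


def field_to_dataarray(field: GriddedField, name: str = "value") -> xr.DataArray:
    da = xr.DataArray(
        field.values,
        dims=("lat", "lon"),
        coords={"lat": field.grid.lat, "lon": field.grid.lon},
        name=name,
        attrs={"units": field.units, "kind": field.kind, "case": field.case,
               "difference": int(field.difference)},
    )
    da["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    da["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    return da


def dataarray_to_field(da: xr.DataArray) -> GriddedField:
    grid = GridSpec(np.asarray(da["lat"]), np.asarray(da["lon"]))
    vals = np.asarray(da.transpose("lat", "lon"))
    return GriddedField(
        grid, vals,
        units=str(da.attrs.get("units", "")),
        kind=str(da.attrs.get("kind", "intensive")),
        case=str(da.attrs.get("case", "")),
        difference=bool(da.attrs.get("difference", 0)),
    )


def write_field(field: GriddedField, path: str | Path, name: str = "value") -> None:
    field_to_dataarray(field, name).to_dataset(name=name).to_netcdf(
        path, engine="scipy"
    )


def read_field(path: str | Path, name: str | None = None) -> GriddedField:
    with xr.open_dataset(path, engine="scipy") as ds:
        if name is None:
            data_vars = list(ds.data_vars)
            if len(data_vars) != 1:
                raise ValueError(f"file has variables {data_vars}; pass a name")
            name = data_vars[0]
        return dataarray_to_field(ds[name].load())
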