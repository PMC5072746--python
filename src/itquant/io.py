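"""Readers and writers for series (CSV), grids (NetCDF) and results.

Series travel as two-column CSV (``time,value``; missing as empty or NA);
grids as CF-style NetCDF with a time x lat x lon variable (written through
xarray's scipy backend, netCDF3 classic).  Result files carry a provenance
comment header (package version and parameters) so deterministic outputs can
be reproduced bitwise.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gridded import GriddedField, ITQMaps
from .ordinal import OrdinalDistribution, TimeSeries, lehmer_unrank

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_grid_netcdf",
    "write_grid_netcdf",
    "write_distribution_csv",
    "write_itqmaps_netcdf",
    "provenance_header",
]

_FLOAT_FMT = "%.12g"  # 12 significant digits keeps CSV round-trips stable


def provenance_header(command: str, **params) -> str:
    """Comment lines recording package version and run parameters."""
    items = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# itquant v{__version__} | {command} | {items}\n"


def read_timeseries_csv(path) -> TimeSeries:
    """Read a ``time,value`` CSV into a :class:`TimeSeries`.

    Missing values may be empty fields or NA/NaN tokens.  The time column
    must be strictly increasing; a non-uniform step triggers a warning (the
    mean step is used), a non-monotone time column is an error.
    """
    import warnings

    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "time" not in cols or "value" not in cols:
        raise ValueError("CSV must have 'time' and 'value' columns")
    t = pd.to_numeric(df[cols["time"]], errors="raise").to_numpy(dtype=float)
    v = pd.to_numeric(df[cols["value"]], errors="coerce").to_numpy(dtype=float)
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time column must be strictly increasing")
        step = float(dt.mean())
        if not np.allclose(dt, step, rtol=1e-6):
            warnings.warn("non-uniform time step; using the mean step")
    else:
        step = 1.0
    return TimeSeries(v, step=step, missing_mask=np.isnan(v))


def write_timeseries_csv(series: TimeSeries, path, command: str = "simulate",
                         **params) -> None:
    path = Path(path)
    t = np.arange(len(series)) * series.step
    with open(path, "w") as fh:
        fh.write(provenance_header(command, step=series.step,
                                   step_unit=series.step_unit, **params))
        fh.write("time,value\n")
        for ti, vi, mi in zip(t, series.values, series.missing_mask):
            val = "" if mi else _FLOAT_FMT % vi
            fh.write(f"{_FLOAT_FMT % ti},{val}\n")


def write_distribution_csv(dist: OrdinalDistribution, path, **params) -> None:
    """Serialize a pattern distribution: rank, permutation, probability, raw."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header("distribution", D=dist.D, tau=dist.tau,
                                   ordering=dist.ordering,
                                   weighted=dist.weighted,
                                   n_windows=dist.n_windows, **params))
        fh.write("pattern_rank,permutation,probability,count_or_weight\n")
        for rank in range(dist.n_patterns):
            if dist.ordering == "lehmer":
                perm = "-".join(map(str, lehmer_unrank(rank, dist.D)))
            else:
                perm = ""
            fh.write(
                f"{rank},{perm},{_FLOAT_FMT % dist.p[rank]},"
                f"{_FLOAT_FMT % dist.raw[rank]}\n"
            )


def _find_dim(ds_dims, candidates):
    for c in candidates:
        for d in ds_dims:
            if d.lower() == c:
                return d
    return None


def read_grid_netcdf(path, variable: str) -> GriddedField:
    """Read one time x lat x lon variable from a NetCDF file.

    Dimensions are identified by name (time / lat(itude) / lon(gitude)) and
    transposed into (time, lat, lon) order if stored differently; fill
    values become missing.
    """
    import xarray as xr

    with xr.open_dataset(path) as ds:
        if variable not in ds:
            raise ValueError(
                f"variable {variable!r} not found; available: "
                f"{sorted(ds.data_vars)}"
            )
        da = ds[variable]
        if da.ndim != 3:
            raise ValueError(f"variable {variable!r} must have 3 dimensions")
        tdim = _find_dim(da.dims, ("time", "t", "month"))
        ydim = _find_dim(da.dims, ("lat", "latitude", "y"))
        xdim = _find_dim(da.dims, ("lon", "longitude", "x"))
        if None in (tdim, ydim, xdim):
            raise ValueError(
                f"cannot identify time/lat/lon among dims {da.dims}"
            )
        da = da.transpose(tdim, ydim, xdim)
        values = da.values.astype(float)
        return GriddedField(
            values=values,
            time=np.asarray(da[tdim].values),
            lat=np.asarray(da[ydim].values, dtype=float),
            lon=np.asarray(da[xdim].values, dtype=float),
            name=variable,
            units=str(da.attrs.get("units", "")),
        )


def write_grid_netcdf(grid: GriddedField, path) -> None:
    """Write a grid as netCDF3 classic (xarray scipy backend)."""
    ds = grid.to_dataset()
    ds.attrs["source"] = f"itquant v{__version__}"
    ds.to_netcdf(path, engine="scipy")


def write_itqmaps_netcdf(maps: ITQMaps, path) -> None:
    """Write H/C/F maps as one netCDF3 dataset."""
    import xarray as xr

    coords = {"lat": maps.lat, "lon": maps.lon}
    data = {
        k: xr.DataArray(np.where(maps.missing_mask, np.nan, v),
                        dims=("lat", "lon"), coords=coords)
        for k, v in (("H", maps.H), ("C", maps.C), ("F", maps.F))
    }
    ds = xr.Dataset(data)
    ds.attrs.update(
        source=f"itquant v{__version__}",
        D=maps.config.D,
        tau=maps.config.tau,
        weighted=int(maps.config.weighted),
    )
    ds.to_netcdf(path, engine="scipy")
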