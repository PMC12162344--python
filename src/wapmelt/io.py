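"""Readers and writers for the formats the pipeline touches.

Gridded fields travel as CF-style netCDF (time, lat, lon); tabular data as
comma-separated UTF-8 CSV with '.' decimals, ISO 8601 dates and empty
fields for missing values; reports as JSON.  Every writer's output is
readable by its reader with value equality.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .errors import FormatError
from .icepheno import SeaIceSeries

_NC_ENGINE = "scipy"  # NETCDF3_CLASSIC


def read_gridded(path, var: str | None = None) -> xr.DataArray:
    """Read a CF-style gridded variable with (time, lat, lon) coordinates.

    ``var`` selects a variable by name; defaults to the single data
    variable present.  A missing coordinate axis raises
    :class:`FormatError` naming the axis.
    """
    ds = xr.open_dataset(path, engine=_NC_ENGINE)
    for ax in ("time", "lat", "lon"):
        if ax not in ds.coords and ax not in ds.dims:
            raise FormatError(f"{path}: gridded file lacks the '{ax}' axis")
    if var is None:
        names = list(ds.data_vars)
        if len(names) != 1:
            raise FormatError(
                f"{path}: specify var= among {names}")
        var = names[0]
    elif var not in ds.data_vars:
        raise FormatError(f"{path}: no variable {var!r}")
    da = ds[var].load()
    ds.close()
    return da.transpose("time", "lat", "lon")


def write_gridded(da: xr.DataArray, path, var: str = "value") -> None:
    da = da.rename(var)
    # netCDF3 has no NaN-safe int64 time; let xarray encode the axis
    da.to_netcdf(path, engine=_NC_ENGINE)


def read_samples_csv(path) -> pd.DataFrame:
    """Bottle-sample table: sample_id, date, latitude, longitude, depth_m,
    salinity_psu, d18o_permil [, chla_ugL]."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = ["sample_id", "date", "latitude", "longitude", "depth_m",
                "salinity_psu", "d18o_permil"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    return df


def write_fractions_csv(samples: pd.DataFrame, fractions: pd.DataFrame,
                        path) -> None:
    """Input rows mirrored with f_sim, f_met, f_ow, residual, out_of_range
    appended (decomposition CSV contract)."""
    out = samples.reset_index(drop=True).copy()
    add = fractions.reset_index(drop=True)
    for c in ("f_sim", "f_met", "f_ow", "residual", "out_of_range", "error"):
        out[c] = add[c]
    out.to_csv(path, index=False)


def read_sic_csv(path) -> SeaIceSeries:
    """Single-cell SIC series: columns date, sic_percent."""
    df = pd.read_csv(path)
    for c in ("date", "sic_percent"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")
    return SeaIceSeries(pd.to_datetime(df["date"], format="ISO8601"),
                        df["sic_percent"].to_numpy(dtype=float))


def write_sic_csv(series: SeaIceSeries, path) -> None:
    df = series.to_frame()[["date", "sic_percent"]]
    df.to_csv(path, index=False, date_format="%Y-%m-%d")


def read_profile_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """One hydrographic profile: (depth_m, density_kgm3) or
    (depth_m, temperature_c, salinity_psu)."""
    df = pd.read_csv(path)
    if "depth_m" not in df.columns:
        raise FormatError(f"{path}: missing column 'depth_m'")
    depth = df["depth_m"].to_numpy(dtype=float)
    if "density_kgm3" in df.columns:
        return depth, df["density_kgm3"].to_numpy(dtype=float)
    if {"temperature_c", "salinity_psu"} <= set(df.columns):
        from .mld import density_from_ts
        return depth, density_from_ts(df["temperature_c"].to_numpy(float),
                                      df["salinity_psu"].to_numpy(float))
    raise FormatError(f"{path}: need density_kgm3 or temperature_c+"
                      "salinity_psu columns")


def write_regional_series_csv(series: pd.DataFrame, variable: str,
                              path) -> None:
    """Tidy time-series CSV: date, variable, value, n_cells,
    coverage_fraction."""
    out = series.reset_index()
    out.insert(1, "variable", variable)
    out.to_csv(path, index=False, date_format="%Y-%m-%d",
               float_format="%.10g")


def read_regional_series_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    return df.set_index("date")


def write_report_json(report: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=default) + "\n")


def read_report_json(path) -> dict:
    return json.loads(Path(path).read_text())
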