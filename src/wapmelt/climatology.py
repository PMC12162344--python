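"""Regional reduction of gridded fields and austral-year climatology.

Gridded fields (time × lat × lon, as :class:`xarray.DataArray`) are reduced
to regional time series by a cos(latitude)-weighted mean over the cells
whose centres fall inside a region-of-interest polygon.  Downstream
summaries follow the Southern Hemisphere growing season: the *austral year*
Y runs 1 September Y through 31 August Y+1, and *summer* is December of Y
with January–February of Y+1 (DJF).  Percent anomalies compare a summer
mean with a long-term climatological mean:

    anomaly% = (summer mean − climatological mean) / climatological mean × 100

Regional series are plain :class:`pandas.DataFrame` objects with a ``date``
index and columns ``value`` (the weighted mean, NaN where no cells were
observed), ``n_cells`` and ``coverage_fraction`` — the common currency
between this module, the statistics module and the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Point, Polygon

from .errors import (CoverageError, GeometryError, InvalidInputError,
                     UndefinedAnomalyError)


@dataclass(frozen=True)
class RegionOfInterest:
    """A lon/lat polygon; vertices in degrees, closed automatically."""

    vertices: tuple[tuple[float, float], ...]

    def __init__(self, vertices) -> None:
        verts = [tuple(map(float, v)) for v in vertices]
        if len(verts) >= 2 and verts[0] == verts[-1]:
            verts = verts[:-1]  # drop explicit closure
        if len(verts) < 3:
            raise GeometryError("ROI needs >= 3 distinct vertices")
        object.__setattr__(self, "vertices", tuple(verts))
        if not self.polygon.is_valid:
            raise GeometryError("ROI polygon is self-intersecting")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def contains_mask(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Boolean (lat, lon) mask of cell centres inside the polygon."""
        poly = self.polygon
        lon2, lat2 = np.meshgrid(lon, lat)
        flat = [poly.covers(Point(x, y))
                for x, y in zip(lon2.ravel(), lat2.ravel())]
        return np.array(flat).reshape(lat.size, lon.size)


#: The study region: the Palmer LTER sampling grid along the WAP shelf.
WAP_ROI = RegionOfInterest([(-66.86, -63.97), (-78.48, -68.09),
                            (-76.14, -69.24)])


def _check_field(field: xr.DataArray) -> xr.DataArray:
    for ax in ("time", "lat", "lon"):
        if ax not in field.dims:
            raise InvalidInputError(f"field is missing the '{ax}' dimension")
    return field.transpose("time", "lat", "lon")


def regional_mean(field: xr.DataArray, roi: RegionOfInterest,
                  land_mask: xr.DataArray | None = None,
                  min_coverage: float = 0.0) -> pd.DataFrame:
    """cos(latitude)-weighted ROI mean per time step.

    Parameters
    ----------
    field
        Gridded values with dims (time, lat, lon); NaN marks missing.
    roi
        Polygon selecting cells by centre.
    land_mask
        Optional boolean (lat, lon) array, True over ocean; land cells are
        excluded from the ROI.
    min_coverage
        Time steps observing a smaller fraction of ROI cells than this are
        set to missing.  Default 0: any observed cell yields a value.

    Returns
    -------
    DataFrame indexed by date with columns ``value``, ``n_cells``,
    ``coverage_fraction``.
    """
    field = _check_field(field)
    lat = field["lat"].to_numpy()
    lon = field["lon"].to_numpy()
    inside = roi.contains_mask(lat, lon)
    if land_mask is not None:
        inside = inside & np.asarray(land_mask, dtype=bool)
    n_roi = int(inside.sum())
    if n_roi == 0:
        raise GeometryError("ROI does not overlap the field grid")

    w = np.cos(np.deg2rad(lat))[:, None] * np.ones((1, lon.size))
    w = np.where(inside, w, 0.0)
    vals = field.to_numpy()  # (t, lat, lon)
    obs = np.isfinite(vals) & inside  # observed ROI cells per step
    wt = np.where(obs, w[None, :, :], 0.0)
    wsum = wt.sum(axis=(1, 2))
    num = np.nansum(np.where(obs, vals, 0.0) * wt, axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = num / wsum
    n_cells = obs.sum(axis=(1, 2))
    coverage = n_cells / n_roi
    mean = np.where(n_cells == 0, np.nan, mean)
    mean = np.where(coverage < min_coverage, np.nan, mean)
    out = pd.DataFrame({"value": mean, "n_cells": n_cells,
                        "coverage_fraction": coverage},
                       index=pd.DatetimeIndex(field["time"].to_numpy(),
                                              name="date"))
    return out


def austral_year_of(date) -> int:
    """Austral year of a date: year Y covers 1 Sep Y → 31 Aug Y+1."""
    ts = pd.Timestamp(date)
    return ts.year if ts.month >= 9 else ts.year - 1


def summer_mean(series: pd.DataFrame | pd.Series, year: int) -> float:
    """Day-weighted DJF mean of a daily regional series for one austral
    year: December of ``year`` plus January–February of ``year + 1``.
    Missing-aware; NaN when no DJF value is observed."""
    vals = series["value"] if isinstance(series, pd.DataFrame) else series
    idx = pd.DatetimeIndex(vals.index)
    djf = ((idx >= pd.Timestamp(_date(year, 12, 1)))
           & (idx <= pd.Timestamp(_date(year + 1, 2, 29 if
                                        pd.Timestamp(year + 1, 1, 1).is_leap_year
                                        else 28))))
    sel = vals[djf]
    if sel.notna().sum() == 0:
        return float("nan")
    return float(sel.mean())


def anomaly_percent(summer: float, climatological_mean: float) -> float:
    """(summer − climatology) / climatology × 100."""
    if climatological_mean == 0 or not np.isfinite(climatological_mean):
        raise UndefinedAnomalyError(
            "percent anomaly undefined for zero/non-finite climatology")
    return (summer - climatological_mean) / climatological_mean * 100.0


def summer_anomalies(series: pd.DataFrame, years: list[int] | range
                     ) -> pd.Series:
    """Percent summer anomalies by austral year against the all-summer
    climatological mean (the mean of the per-year DJF means)."""
    means = pd.Series({y: summer_mean(series, y) for y in years})
    clim = means.mean()
    return means.apply(lambda m: anomaly_percent(m, clim))


def monthly_mean(series: pd.DataFrame) -> pd.DataFrame:
    """Calendar-month means of a daily regional series (missing-aware)."""
    g = series["value"].resample("MS")
    out = pd.DataFrame({"value": g.mean(), "n_days": g.count()})
    out.index.name = "date"
    return out


def composite_8day(series: pd.DataFrame) -> pd.DataFrame:
    """Means over consecutive 8-day bins anchored at 1 January of each
    calendar year (ocean-colour style; the year's last bin is truncated).

    Returns a DataFrame indexed by bin start date with columns ``value``
    and ``n_days``; a fully missing bin is NaN.
    """
    vals = series["value"] if isinstance(series, pd.DataFrame) else series
    idx = pd.DatetimeIndex(vals.index)
    bin_start = (pd.to_datetime({"year": idx.year, "month": 1, "day": 1})
                 + pd.to_timedelta((idx.dayofyear - 1) // 8 * 8, unit="D"))
    g = vals.groupby(bin_start.to_numpy())
    out = pd.DataFrame({"value": g.mean(), "n_days": g.count()})
    out.index.name = "date"
    return out.sort_index()


def period_climatology(field: xr.DataArray, start, end,
                       roi: RegionOfInterest | None = None
                       ) -> tuple[xr.DataArray, xr.DataArray, dict]:
    """Temporal mean and standard-error maps over a date range, plus the
    regional scalar mean ± SE.

    The per-cell SE is sd/√n over the period's time steps (NaN where fewer
    than 2 observations).  The regional scalar is the ROI mean of the mean
    map; its SE is computed from the ROI-averaged daily series, which
    respects the day-to-day correlation structure of regional averages.
    """
    field = _check_field(field)
    t = pd.DatetimeIndex(field["time"].to_numpy())
    sel = (t >= pd.Timestamp(start)) & (t <= pd.Timestamp(end))
    if not sel.any():
        raise CoverageError("period does not intersect the field time axis")
    sub = field.isel(time=np.flatnonzero(sel))
    mean_map = sub.mean("time", skipna=True)
    n = sub.notnull().sum("time")
    import warnings
    with warnings.catch_warnings():
        # cells with a single observation have no sample sd; they are
        # masked below, so the ddof warning is expected noise
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = sub.std("time", skipna=True, ddof=1)
    se_map = (sd / np.sqrt(n)).where(n >= 2)
    regional = {}
    if roi is not None:
        daily = regional_mean(sub, roi)
        v = daily["value"].dropna()
        regional = {
            "mean": float(regional_mean(
                mean_map.expand_dims(time=[t[sel][0]]), roi)["value"].iloc[0]),
            "se": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) >= 2
                  else float("nan"),
            "n_days": int(len(v)),
        }
    return mean_map, se_map, regional
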