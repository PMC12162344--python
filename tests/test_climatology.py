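"""Regional means, austral calendar, anomalies, composites."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from wapmelt.climatology import (RegionOfInterest, WAP_ROI, anomaly_percent,
                                 austral_year_of, composite_8day,
                                 monthly_mean, period_climatology,
                                 regional_mean, summer_mean)
from wapmelt.errors import (CoverageError, GeometryError,
                            UndefinedAnomalyError)


def toy_field(values, lat, lon, dates):
    return xr.DataArray(values, dims=("time", "lat", "lon"),
                        coords={"time": dates, "lat": lat, "lon": lon})


def box_roi(lat, lon, pad=0.5):
    return RegionOfInterest([(lon.min() - pad, lat.min() - pad),
                             (lon.max() + pad, lat.min() - pad),
                             (lon.max() + pad, lat.max() + pad),
                             (lon.min() - pad, lat.max() + pad)])


class TestRegionalMean:
    def test_constant_field(self):
        lat = np.array([-66.0, -65.0])
        lon = np.array([-70.0, -69.0])
        dates = pd.date_range("2010-01-01", periods=3)
        f = toy_field(np.full((3, 2, 2), 3.0), lat, lon, dates)
        rs = regional_mean(f, box_roi(lat, lon))
        assert np.allclose(rs["value"], 3.0)
        assert (rs["n_cells"] == 4).all()
        assert np.allclose(rs["coverage_fraction"], 1.0)

    def test_two_cells_equal_latitude(self):
        lat = np.array([-65.0])
        lon = np.array([-70.0, -69.0])
        dates = pd.date_range("2010-01-01", periods=1)
        f = toy_field(np.array([[[1.0, 3.0]]]), lat, lon, dates)
        rs = regional_mean(f, box_roi(lat, lon))
        assert rs["value"].iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_cos_latitude_weighting(self):
        lat = np.array([-80.0, 0.0])
        lon = np.array([-70.0])
        dates = pd.date_range("2010-01-01", periods=1)
        f = toy_field(np.array([[[2.0], [4.0]]]), lat, lon, dates)
        rs = regional_mean(f, box_roi(lat, lon))
        w80, w0 = np.cos(np.deg2rad(80.0)), 1.0
        want = (2.0 * w80 + 4.0 * w0) / (w80 + w0)
        assert rs["value"].iloc[0] == pytest.approx(want, abs=1e-12)

    def test_all_missing_step_is_missing(self):
        lat = np.array([-65.0, -64.0])
        lon = np.array([-70.0])
        dates = pd.date_range("2010-01-01", periods=2)
        vals = np.full((2, 2, 1), 5.0)
        vals[1] = np.nan
        rs = regional_mean(toy_field(vals, lat, lon, dates),
                           box_roi(lat, lon))
        assert np.isnan(rs["value"].iloc[1])
        assert rs["n_cells"].iloc[1] == 0

    def test_no_overlap_raises(self):
        lat = np.array([40.0, 41.0])
        lon = np.array([3.0, 4.0])
        f = toy_field(np.zeros((1, 2, 2)), lat, lon,
                      pd.date_range("2010-01-01", periods=1))
        with pytest.raises(GeometryError):
            regional_mean(f, WAP_ROI)

    def test_linearity(self):
        """regional_mean(a*field + b) == a*regional_mean(field) + b."""
        rng = np.random.default_rng(5)
        lat = np.arange(-68.0, -63.9, 1.0)
        lon = np.arange(-75.0, -69.9, 1.0)
        dates = pd.date_range("2010-01-01", periods=4)
        vals = rng.normal(size=(4, lat.size, lon.size))
        f = toy_field(vals, lat, lon, dates)
        roi = box_roi(lat, lon)
        base = regional_mean(f, roi)["value"].to_numpy()
        scaled = regional_mean(2.5 * f + 1.25, roi)["value"].to_numpy()
        assert np.abs(scaled - (2.5 * base + 1.25)).max() < 1e-12

    def test_land_mask_excludes_cells(self):
        lat = np.array([-65.0])
        lon = np.array([-70.0, -69.0])
        dates = pd.date_range("2010-01-01", periods=1)
        f = toy_field(np.array([[[1.0, 3.0]]]), lat, lon, dates)
        mask = np.array([[True, False]])  # second cell is land
        rs = regional_mean(f, box_roi(lat, lon), land_mask=mask)
        assert rs["value"].iloc[0] == pytest.approx(1.0)


class TestAustralCalendar:
    @pytest.mark.parametrize("date,year", [
        ("2015-09-01", 2015), ("2016-08-31", 2015), ("2016-02-29", 2015),
        ("2016-09-01", 2016), ("2002-01-01", 2001),
    ])
    def test_boundaries(self, date, year):
        assert austral_year_of(date) == year

    def test_totality_2002_2022(self):
        """Every date maps to exactly one austral year, and consecutive
        austral years partition the calendar."""
        dates = pd.date_range("2002-01-01", "2022-12-31")
        ay = np.array([austral_year_of(d) for d in dates])
        assert set(np.unique(np.diff(ay))) <= {0, 1}
        for y in range(2002, 2022):
            days = (ay == y).sum()
            assert days in (365, 366)


class TestSummerAndAnomaly:
    def _series(self, values_by_month):
        dates = pd.date_range("2014-09-01", "2015-08-31")
        vals = np.array([values_by_month(d.month) for d in dates], float)
        return pd.DataFrame({"value": vals}, index=dates)

    def test_constant_series(self):
        s = self._series(lambda m: 4.2)
        assert summer_mean(s, 2014) == pytest.approx(4.2)

    def test_day_weighted_djf(self):
        """Dec=1, Jan=2, Feb=3 daily constants: the mean is weighted by
        day counts (31/31/28 in a non-leap February)."""
        s = self._series(lambda m: {12: 1.0, 1: 2.0, 2: 3.0}.get(m, np.nan))
        want = (31 * 1.0 + 31 * 2.0 + 28 * 3.0) / 90.0
        assert summer_mean(s, 2014) == pytest.approx(want, abs=1e-12)

    def test_all_djf_missing(self):
        s = self._series(lambda m: np.nan if m in (12, 1, 2) else 1.0)
        assert np.isnan(summer_mean(s, 2014))

    def test_anomaly_identities(self):
        assert anomaly_percent(0.7, 0.7) == pytest.approx(0.0)
        assert anomaly_percent(1.4, 0.7) == pytest.approx(100.0)
        assert anomaly_percent(0.73, 0.70) == pytest.approx(100 * 0.03 / 0.70)

    def test_zero_climatology_raises(self):
        with pytest.raises(UndefinedAnomalyError):
            anomaly_percent(1.0, 0.0)


class TestComposites:
    def test_first_bin_mean(self):
        dates = pd.date_range("2010-01-01", periods=16)
        s = pd.DataFrame({"value": np.arange(1.0, 17.0)}, index=dates)
        comp = composite_8day(s)
        assert comp["value"].iloc[0] == pytest.approx(4.5)
        assert comp["value"].iloc[1] == pytest.approx(12.5)
        assert comp.index[0] == pd.Timestamp("2010-01-01")
        assert comp.index[1] == pd.Timestamp("2010-01-09")

    def test_constant_series_constant_composites(self):
        dates = pd.date_range("2010-01-01", "2010-12-31")
        s = pd.DataFrame({"value": np.full(len(dates), 2.0)}, index=dates)
        comp = composite_8day(s)
        assert np.allclose(comp["value"], 2.0)
        # bins re-anchor at 1 January: 46 bins in a 365-day year
        assert len(comp) == 46

    def test_fully_missing_bin(self):
        dates = pd.date_range("2010-01-01", periods=16)
        vals = np.arange(1.0, 17.0)
        vals[8:16] = np.nan
        comp = composite_8day(pd.DataFrame({"value": vals}, index=dates))
        assert np.isnan(comp["value"].iloc[1])

    def test_monthly_partition_consistency(self):
        """Monthly means from daily values equal direct month-group means."""
        rng = np.random.default_rng(11)
        dates = pd.date_range("2011-01-01", "2012-12-31")
        vals = rng.normal(size=len(dates))
        s = pd.DataFrame({"value": vals}, index=dates)
        got = monthly_mean(s)["value"]
        direct = s["value"].groupby([s.index.year, s.index.month]).mean()
        assert np.allclose(got.to_numpy(), direct.to_numpy())


class TestPeriodClimatology:
    def _field(self, vals, dates):
        lat = np.array([-66.0, -65.0])
        lon = np.array([-70.0, -69.0])
        return toy_field(vals, lat, lon, dates), box_roi(lat, lon)

    def test_constant_field(self):
        dates = pd.date_range("2010-01-01", periods=5)
        f, roi = self._field(np.full((5, 2, 2), 7.0), dates)
        mean_map, se_map, reg = period_climatology(f, "2010-01-01",
                                                   "2010-01-05", roi)
        assert np.allclose(mean_map, 7.0)
        assert np.allclose(se_map, 0.0)
        assert reg["mean"] == pytest.approx(7.0)
        assert reg["se"] == pytest.approx(0.0)

    def test_two_steps_sd_over_sqrt_n(self):
        dates = pd.date_range("2010-01-01", periods=2)
        vals = np.empty((2, 2, 2))
        vals[0], vals[1] = 1.0, 3.0
        f, roi = self._field(vals, dates)
        mean_map, se_map, _ = period_climatology(f, "2010-01-01",
                                                 "2010-01-02", roi)
        assert np.allclose(mean_map, 2.0)
        assert np.allclose(se_map, 1.0)  # sd=sqrt(2), se=sd/sqrt(2)=1

    def test_single_step_se_missing(self):
        dates = pd.date_range("2010-01-01", periods=1)
        f, roi = self._field(np.full((1, 2, 2), 4.0), dates)
        _, se_map, _ = period_climatology(f, "2010-01-01", "2010-01-01", roi)
        assert np.isnan(se_map).all()

    def test_empty_period_raises(self):
        dates = pd.date_range("2010-01-01", periods=3)
        f, roi = self._field(np.zeros((3, 2, 2)), dates)
        with pytest.raises(CoverageError):
            period_climatology(f, "2015-01-01", "2015-02-01", roi)
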