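"""Sea-ice phenology: detectors vs brute force, sentinels, trends."""

import calendar

import numpy as np
import pandas as pd
import pytest

from wapmelt.errors import (CoverageError, InsufficientDataError,
                            InvalidInputError)
from wapmelt.icepheno import (SeaIceSeries, SearchWindow, detect_advance,
                              detect_retreat, fill_gaps, fit_annual_trend,
                              ice_season_duration, season_indices,
                              window_end_jd)
from wapmelt.synth import make_sic_series, random_sic_truths


def series_from_jd(anchor_year, values_by_jd):
    """Build a daily series over the window from a jd->sic mapping."""
    w = SearchWindow(anchor_year)
    jd = np.arange(w.start_jd, w.end_jd + 1)
    sic = np.array([values_by_jd(d) for d in jd], dtype=float)
    return SeaIceSeries(w.dates(), sic), w


# -- independent brute-force oracles (exhaustive day-by-day scans) ----------

def brute_advance(sic, start_jd, threshold, persistence):
    for i in range(len(sic) - persistence + 1):
        if all(s > threshold for s in sic[i:i + persistence]):
            return start_jd + i
    return None


def brute_retreat(sic, start_jd, end_jd, threshold):
    above = [s > threshold for s in sic]
    if not any(above):
        return None
    if above[-1]:
        return end_jd
    for i in range(len(sic)):
        if not any(above[i:]):
            return start_jd + i
    return end_jd


class TestDetectors:
    def test_advance_at_day_100(self):
        s, w = series_from_jd(2005, lambda d: 80.0 if 100 <= d < 120 else 0.0)
        assert detect_advance(s, w) == 100

    def test_retreat_at_day_300(self):
        s, w = series_from_jd(2005, lambda d: 80.0 if d < 300 else 5.0)
        assert detect_retreat(s, w) == 300

    def test_perennial_ice_gets_window_sentinels(self):
        s, w = series_from_jd(2005, lambda d: 100.0)
        assert detect_advance(s, w) == 46
        assert detect_retreat(s, w) == 410  # non-leap anchor year

    def test_ice_free_gets_no_ice_marker(self):
        s, w = series_from_jd(2005, lambda d: 0.0)
        assert detect_advance(s, w) is None
        assert detect_retreat(s, w) is None
        idx = season_indices(s, 2005)
        assert idx.reason == "no_ice" and idx.duration_days == 0

    def test_exactly_threshold_counts_as_below(self):
        s, w = series_from_jd(2005, lambda d: 15.0)
        assert detect_advance(s, w) is None

    def test_short_excursion_below_persistence_ignored(self):
        s, w = series_from_jd(2005, lambda d: 80.0 if 100 <= d < 104 else 0.0)
        assert detect_advance(s, w, persistence=5) is None
        assert detect_advance(s, w, persistence=4) == 100

    def test_window_not_covered_raises(self):
        dates = pd.date_range("2005-03-01", "2005-06-01")
        s = SeaIceSeries(dates, np.zeros(len(dates)))
        with pytest.raises(CoverageError):
            detect_advance(s, SearchWindow(2005))

    def test_oracle_equivalence_on_random_series(self):
        """Detected dates equal exhaustive scans on noisy synthetic series."""
        w = SearchWindow(2006)
        for i, (adv, ret) in enumerate(random_sic_truths(50, 2006, seed=7)):
            s, _ = make_sic_series(2006, adv, ret, noise_sd=3.0, margin=10.0,
                                   seed=i)
            sic = list(s.sic)
            assert detect_advance(s, w) == brute_advance(sic, 46, 15.0, 5)
            assert detect_retreat(s, w) == brute_retreat(sic, 46, w.end_jd,
                                                         15.0)

    def test_threshold_monotonicity(self):
        """Raising the ice-edge threshold never moves advance earlier."""
        for i, (adv, ret) in enumerate(random_sic_truths(20, 2006, seed=8)):
            s, _ = make_sic_series(2006, adv, ret, plateau=90.0, noise_sd=5.0,
                                   margin=12.0, seed=100 + i)
            w = SearchWindow(2006)
            prev = None
            for thr in (15.0, 25.0, 40.0, 60.0):
                a = detect_advance(s, w, threshold=thr)
                if prev is not None and a is not None:
                    assert a >= prev
                if a is None:
                    prev = 10**6  # once undetectable, stays undetectable
                else:
                    prev = a


class TestWindowAndDuration:
    def test_leap_rule_1979_2022(self):
        for y in range(1979, 2023):
            assert window_end_jd(y) == (411 if calendar.isleap(y) else 410)

    def test_sentinel_duration_perennial_vs_ice_free(self):
        s, w = series_from_jd(2004, lambda d: 100.0)  # 2004 is a leap year
        idx = season_indices(s, 2004)
        assert (idx.advance_jd, idx.retreat_jd) == (46, 411)
        assert idx.duration_days == 411 - 46

    def test_duration_arithmetic(self):
        assert ice_season_duration(46, 410) == 364
        assert ice_season_duration(100, 300) == 200
        assert ice_season_duration(100, 100) == 0
        assert ice_season_duration(None, None) == 0

    def test_duration_mismatched_years_raises(self):
        with pytest.raises(InvalidInputError):
            ice_season_duration(100, 300, advance_year=2001,
                                retreat_year=2002)


class TestFillGaps:
    def test_every_other_day_interpolated_and_flagged(self):
        dates = pd.date_range("2005-01-01", periods=5, freq="2D")
        s = fill_gaps(SeaIceSeries(dates, [50, 50, 50, 50, 50]))
        assert len(s.dates) == 9
        assert np.allclose(s.sic, 50.0)
        assert list(s.interpolated) == [False, True] * 4 + [False]

    def test_linear_midpoint(self):
        dates = pd.DatetimeIndex(["2005-01-01", "2005-01-03"])
        s = fill_gaps(SeaIceSeries(dates, [0.0, 100.0]))
        assert s.sic[1] == pytest.approx(50.0)

    def test_daily_series_unchanged(self):
        dates = pd.date_range("2005-01-01", periods=10)
        vals = np.linspace(0, 90, 10)
        s = fill_gaps(SeaIceSeries(dates, vals))
        assert np.array_equal(s.sic, vals)
        assert not s.interpolated.any()

    def test_long_gap_raises(self):
        dates = pd.DatetimeIndex(["2005-01-01", "2005-01-10"])
        with pytest.raises(CoverageError):
            fill_gaps(SeaIceSeries(dates, [10.0, 20.0]))


class TestTrend:
    def test_exact_line(self):
        years = pd.Series({y: 2.0 * y + 5.0 for y in range(2000, 2020)})
        slope, intercept, p = fit_annual_trend(years)
        assert slope == pytest.approx(2.0, abs=1e-10)
        assert intercept == pytest.approx(5.0, abs=1e-6)
        assert p < 1e-10

    def test_constant_series_zero_slope(self):
        slope, _, _ = fit_annual_trend(
            pd.Series({y: 7.0 for y in range(2000, 2010)}))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_missing_years_dropped(self):
        s = pd.Series({2000: 1.0, 2001: np.nan, 2002: 3.0, 2003: 4.0})
        slope, _, _ = fit_annual_trend(s)
        assert slope == pytest.approx(1.0, abs=1e-10)

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_annual_trend(pd.Series({2000: 1.0, 2001: 2.0}))

    def test_monte_carlo_recovers_generative_slope(self):
        """500 noisy 44-year series with true slope -1.62: the mean fitted
        slope lands within +-0.2 of truth."""
        rng = np.random.default_rng(99)
        years = np.arange(1979, 2023)
        slopes = []
        for _ in range(500):
            y = -1.62 * (years - years[0]) + 300 + rng.normal(0, 20, len(years))
            slope, _, _ = fit_annual_trend(pd.Series(y, index=years))
            slopes.append(slope)
        assert np.mean(slopes) == pytest.approx(-1.62, abs=0.2)
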