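"""Sea-ice phenology: annual advance, retreat and duration indices.

Annual indices are extracted from (quasi-)daily sea-ice concentration (SIC)
series within a search window anchored at the mean summer sea-ice minimum:
Julian day 46 (15 February of the anchor year) through Julian day 410, or
411 when the anchor year is a leap year — both landing on 14 February of
the following year.  Julian days here are day-of-year of the anchor year,
continuing past 31 December (366, 367, …).

Within the window the *advance* date is the first day on which SIC exceeds
a threshold (default 15 %, the approximate ice edge) for at least a
persistence period (default 5 consecutive days); the *retreat* date is the
first day from which SIC remains strictly below the threshold through the
window end.  Cells where ice never departs take the window limits as
sentinels; cells where ice never arrives get a no-ice marker and a duration
of zero.  Duration is simply retreat minus advance.

Threshold comparisons are strict on both sides: "exceeds" means > threshold
and "below" means < threshold, so a value exactly at the threshold counts
as below the ice edge.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import CoverageError, InsufficientDataError, InvalidInputError

DEFAULT_THRESHOLD = 15.0   # % SIC, approximate ice edge
DEFAULT_PERSISTENCE = 5    # days
WINDOW_START_JD = 46       # 15 February of the anchor year
MAX_GAP_DAYS = 3           # longest gap fill_gaps will interpolate across


def window_end_jd(anchor_year: int) -> int:
    """Search-window end: Julian day 410, or 411 in a leap anchor year.

    A leap anchor year contains 29 February inside the window, shifting
    every later calendar date one Julian day; both 410 (non-leap) and 411
    (leap) correspond to 14 February of the following year.
    """
    return 411 if calendar.isleap(anchor_year) else 410


def jd_to_date(anchor_year: int, jd: int) -> date:
    """Convert an anchor-year Julian day (may exceed 365/366) to a date."""
    return date(anchor_year, 1, 1) + timedelta(days=int(jd) - 1)


def date_to_jd(anchor_year: int, d: date) -> int:
    """Day-of-year of ``d`` counted from 1 January of the anchor year."""
    return (d - date(anchor_year, 1, 1)).days + 1


@dataclass(frozen=True)
class SearchWindow:
    """Annual phenology search window in anchor-year Julian days."""

    anchor_year: int
    start_jd: int = WINDOW_START_JD
    end_jd: int | None = None

    def __post_init__(self) -> None:
        if self.end_jd is None:
            object.__setattr__(self, "end_jd", window_end_jd(self.anchor_year))
        if not self.start_jd < self.end_jd:
            raise InvalidInputError("window start_jd must precede end_jd")

    @property
    def n_days(self) -> int:
        return self.end_jd - self.start_jd + 1

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(jd_to_date(self.anchor_year, self.start_jd),
                             jd_to_date(self.anchor_year, self.end_jd))


@dataclass
class SeaIceSeries:
    """A dated SIC series (%, 0–100); missing values allowed as NaN."""

    dates: pd.DatetimeIndex
    sic: np.ndarray
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.sic = np.asarray(self.sic, dtype=float)
        if len(self.dates) != len(self.sic):
            raise InvalidInputError("dates and sic must have equal length")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise InvalidInputError("dates must be strictly increasing")
        present = self.sic[np.isfinite(self.sic)]
        if present.size and (present.min() < 0 or present.max() > 100):
            raise InvalidInputError("sic must lie in [0, 100] where present")
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.sic), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "sic_percent": self.sic,
                             "interpolated": self.interpolated})


@dataclass(frozen=True)
class IceSeasonIndices:
    """Per-year phenology record.  ``advance_jd``/``retreat_jd`` are None
    when ice never formed (``reason = 'no_ice'``)."""

    year: int
    advance_jd: int | None
    retreat_jd: int | None
    duration_days: int
    reason: str = ""


def fill_gaps(series: SeaIceSeries, max_gap_days: int = MAX_GAP_DAYS
              ) -> SeaIceSeries:
    """Return a daily series, linearly interpolating short gaps in time.

    Handles the every-other-day cadence of early passive-microwave records.
    Interpolated days are flagged.  A run of consecutive missing days longer
    than ``max_gap_days`` raises :class:`CoverageError`.
    """
    s = pd.Series(series.sic, index=series.dates)
    daily = s.resample("1D").asfreq()
    missing = daily.isna()
    if missing.any():
        # longest run of consecutive missing days
        runs = missing.astype(int).groupby((~missing).cumsum()).sum()
        if runs.max() > max_gap_days:
            raise CoverageError(
                f"gap of {int(runs.max())} days exceeds max_gap_days="
                f"{max_gap_days}")
    filled = daily.interpolate(method="time", limit_area="inside")
    if filled.isna().any():
        raise CoverageError("series has missing values at its ends")
    return SeaIceSeries(filled.index, filled.to_numpy(),
                        interpolated=missing.to_numpy())


def _window_values(series: SeaIceSeries, window: SearchWindow) -> np.ndarray:
    """Daily SIC over the window; raises CoverageError if not covered."""
    daily = fill_gaps(series)
    wd = window.dates()
    pos = daily.dates.get_indexer(wd)
    if (pos < 0).any():
        raise CoverageError(
            f"series does not cover the {window.anchor_year} search window "
            f"even after gap-filling")
    return daily.sic[pos]


def detect_advance(series: SeaIceSeries, window: SearchWindow,
                   threshold: float = DEFAULT_THRESHOLD,
                   persistence: int = DEFAULT_PERSISTENCE) -> int | None:
    """First window day on which SIC exceeds ``threshold`` for at least
    ``persistence`` consecutive days; None when the criterion is never met
    (no-ice).  Perennially ice-covered windows return the lower sentinel
    ``window.start_jd`` naturally, as the run starts on day one."""
    if not 0 < threshold < 100:
        raise InvalidInputError("threshold must be in (0, 100)")
    if persistence < 1:
        raise InvalidInputError("persistence must be >= 1")
    sic = _window_values(series, window)
    above = sic > threshold
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= persistence:
            return window.start_jd + i - persistence + 1
    return None


def detect_retreat(series: SeaIceSeries, window: SearchWindow,
                   threshold: float = DEFAULT_THRESHOLD) -> int | None:
    """First window day from which SIC stays below the ice edge
    (SIC <= ``threshold``) through the window end; the upper sentinel ``window.end_jd`` when ice
    never departs; None when ice was never present in the window at all."""
    if not 0 < threshold < 100:
        raise InvalidInputError("threshold must be in (0, 100)")
    sic = _window_values(series, window)
    # one consistent edge rule everywhere: ice present iff SIC > threshold,
    # so a value exactly at the threshold counts as below the ice edge
    above = sic > threshold
    if not above.any():
        return None  # ice-free window: no retreat defined
    last_above = int(np.flatnonzero(above)[-1])
    if last_above == len(sic) - 1:
        return window.end_jd  # ice never departs: upper sentinel
    return window.start_jd + last_above + 1


def ice_season_duration(advance_jd: int | None, retreat_jd: int | None,
                        advance_year: int | None = None,
                        retreat_year: int | None = None) -> int:
    """Days elapsed between advance and retreat; 0 when no ice occurred."""
    if advance_year is not None and retreat_year is not None \
            and advance_year != retreat_year:
        raise InvalidInputError("advance and retreat belong to different "
                                "anchor years")
    if advance_jd is None or retreat_jd is None:
        return 0
    if retreat_jd < advance_jd:
        raise InvalidInputError("retreat_jd precedes advance_jd")
    return int(retreat_jd) - int(advance_jd)


def season_indices(series: SeaIceSeries, anchor_year: int,
                   threshold: float = DEFAULT_THRESHOLD,
                   persistence: int = DEFAULT_PERSISTENCE
                   ) -> IceSeasonIndices:
    """Advance, retreat and duration for one anchor year."""
    window = SearchWindow(anchor_year)
    adv = detect_advance(series, window, threshold, persistence)
    if adv is None:
        return IceSeasonIndices(anchor_year, None, None, 0, reason="no_ice")
    ret = detect_retreat(series, window, threshold)
    if ret is None:  # advance without any day >= threshold cannot happen
        ret = window.end_jd
    return IceSeasonIndices(anchor_year, adv, ret,
                            ice_season_duration(adv, ret))


def fit_annual_trend(values_by_year: pd.Series
                     ) -> tuple[float, float, float]:
    """OLS linear trend of an annual index series.

    Parameters
    ----------
    values_by_year
        Index = anchor year (int), values = annual index (e.g. duration in
        days).  Missing years (NaN) are dropped, never interpolated.

    Returns
    -------
    (slope, intercept, p_value)
        Slope in index units per year with the two-sided p-value on the
        slope.
    """
    s = pd.Series(values_by_year).dropna()
    if len(s) < 3:
        raise InsufficientDataError(
            f"trend fit needs >= 3 years, got {len(s)}")
    res = _sps.linregress(s.index.to_numpy(dtype=float),
                          s.to_numpy(dtype=float))
    return float(res.slope), float(res.intercept), float(res.pvalue)


def indices_table(series: SeaIceSeries, years: range | list[int],
                  threshold: float = DEFAULT_THRESHOLD,
                  persistence: int = DEFAULT_PERSISTENCE) -> pd.DataFrame:
    """Phenology indices for several anchor years of one cell as a tidy
    table (year, advance_jd, retreat_jd, duration_days, flags)."""
    rows = []
    for y in years:
        try:
            idx = season_indices(series, y, threshold, persistence)
            rows.append({"year": y, "advance_jd": idx.advance_jd,
                         "retreat_jd": idx.retreat_jd,
                         "duration_days": idx.duration_days,
                         "flags": idx.reason})
        except CoverageError:
            rows.append({"year": y, "advance_jd": None, "retreat_jd": None,
                         "duration_days": None, "flags": "no_coverage"})
    df = pd.DataFrame(rows)
    for c in ("advance_jd", "retreat_jd", "duration_days"):
        df[c] = df[c].astype("Int64")
    return df
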