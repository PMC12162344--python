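"""Synthetic inputs with the statistical structure each pipeline stage
assumes.

Every generator draws from a named substream of a single root seed, emits a
machine-readable truth record alongside the data, and is constructed so the
matching analysis stage can recover the truth within a stated tolerance:

* :func:`make_mixture_samples` — forward-mixes known end-member fraction
  triplets into (salinity, δ18O) bottle samples.
* :func:`make_sic_series` — a sea-ice season with known advance/retreat
  Julian days, plateau concentration, ramped edges and noise truncated so
  every day stays on the correct side of the detection threshold by a
  stated margin.
* :func:`make_profile` — a two-layer density profile with a known
  interface depth (the true MLD).
* :func:`make_coupled_fields` — coupled daily gridded chl-a/sGMW/SST/SAT
  with a prescribed correlation between sGMW and log10 chl-a, a shared
  seasonal cycle, and winter ocean-colour gaps.  The shared cycle is folded
  into the correlation budget so that the prescribed value is the
  correlation of the *total* observed series, the quantity the pipeline
  measures.

These emulate the statistical structure of the real Western Antarctic
Peninsula inputs (passive-microwave sea ice, ocean-colour chl-a and
meltwater fraction, reanalysis temperatures, bottle samples), not their
physics: fields are spatially quasi-uniform with small cell noise, and no
advection, clouds or retrieval error model is attempted.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
import xarray as xr

from .errors import InvalidInputError
from .icepheno import SeaIceSeries, SearchWindow, window_end_jd
from .watermass import EndMemberSet, forward_mix

#: Illustrative WAP end-member signatures (salinity PSU, δ18O ‰) in the
#: range reported by the regional δ18O literature.  SYNTHETIC calibration
#: for examples and tests — any real analysis must supply its own values.
EXAMPLE_ENDMEMBERS = EndMemberSet(
    s_sim=6.0, s_met=0.0, s_ow=34.73,
    d18o_sim=1.9, d18o_met=-16.0, d18o_ow=-0.14)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a single root seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# water-mass mixtures

def random_fraction_triplets(n: int, rng: np.random.Generator,
                             low: float = -0.1) -> np.ndarray:
    """n random triplets summing to 1; the first two components may dip
    slightly negative (down to ``low``) to mimic over-determination noise
    in real tracer data."""
    f_sim = rng.uniform(low, 0.3, n)
    f_met = rng.uniform(low, 0.4, n)
    f_ow = 1.0 - f_sim - f_met
    return np.column_stack([f_sim, f_met, f_ow])


def make_mixture_samples(endmembers: EndMemberSet,
                         fractions: np.ndarray,
                         noise_sd: float = 0.0,
                         seed: int = 0,
                         start_date: str = "2016-01-01",
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-mix fraction triplets into a bottle-sample table.

    Parameters
    ----------
    fractions
        (n, 3) array of (f_sim, f_met, f_ow); each row must sum to 1
        within 1e-9.
    noise_sd
        Gaussian measurement noise added to both salinity (PSU) and δ18O
        (‰).

    Returns
    -------
    (samples, truth)
        ``samples`` follows the bottle-sample CSV contract (sample_id,
        date, latitude, longitude, depth_m, salinity_psu, d18o_permil);
        ``truth`` carries the generating fractions per sample_id.
    """
    f = np.atleast_2d(np.asarray(fractions, dtype=float))
    if f.shape[1] != 3:
        raise InvalidInputError("fractions must be (n, 3)")
    if np.abs(f.sum(axis=1) - 1.0).max() > 1e-9:
        raise InvalidInputError("each fraction triplet must sum to 1")
    rng = substream(seed, "mixture")
    n = len(f)
    s = np.empty(n)
    d = np.empty(n)
    for i, row in enumerate(f):
        _, s[i], d[i] = forward_mix(row, endmembers)
    if noise_sd > 0:
        s = s + rng.normal(0, noise_sd, n)
        d = d + rng.normal(0, noise_sd, n)
    ids = [f"syn{i:05d}" for i in range(n)]
    dates = pd.date_range(start_date, periods=n, freq="D")
    samples = pd.DataFrame({
        "sample_id": ids,
        "date": dates.strftime("%Y-%m-%d"),
        "latitude": np.round(rng.uniform(-69.0, -64.0, n), 4),
        "longitude": np.round(rng.uniform(-78.0, -66.0, n), 4),
        "depth_m": np.full(n, 2.0),
        "salinity_psu": s,
        "d18o_permil": d,
    })
    truth = pd.DataFrame({"sample_id": ids, "f_sim": f[:, 0],
                          "f_met": f[:, 1], "f_ow": f[:, 2]})
    return samples, truth


# ---------------------------------------------------------------------------
# sea-ice concentration series

def make_sic_series(anchor_year: int,
                    advance_jd: int | None,
                    retreat_jd: int | None,
                    plateau: float = 80.0,
                    noise_sd: float = 0.0,
                    cadence: str = "daily",
                    ramp_days: int = 3,
                    threshold: float = 15.0,
                    margin: float = 10.0,
                    seed: int = 0,
                    ) -> tuple[SeaIceSeries, dict]:
    """A one-season SIC series whose phenology is known by construction.

    Concentration is ``plateau`` on days [advance_jd, retreat_jd), ramping
    internally over ``ramp_days`` at each edge but never below
    ``threshold + margin``, and at most ``threshold − margin`` outside the
    season.  Truncated Gaussian noise (clipped to ±0.999·margin) keeps
    every day strictly on its side of the threshold, so the detectors
    recover (advance_jd, retreat_jd) exactly.  ``advance_jd=None`` gives an
    ice-free season; ``plateau`` covering the whole window gives the
    perennial case with sentinel indices 46 and 410/411.

    The every-other-day cadence drops alternate days (emulating early
    passive-microwave sampling) while always retaining the two days
    around each transition, so gap-filling reconstructs the crossings
    exactly.

    Returns the series plus a truth dict with the generating indices.
    """
    window = SearchWindow(anchor_year)
    start, end = window.start_jd, window.end_jd
    ice_free = advance_jd is None
    if not ice_free:
        if retreat_jd is None or not (start <= advance_jd <= retreat_jd <= end):
            raise InvalidInputError(
                f"need {start} <= advance <= retreat <= {end}")
    if not 0 <= margin < threshold:
        raise InvalidInputError("margin must lie in [0, threshold)")
    if not ice_free and plateau < threshold + margin:
        raise InvalidInputError("plateau must be >= threshold + margin")

    jd = np.arange(start, end + 1)
    low = max(0.0, threshold - margin)
    high_floor = threshold + margin
    sic = np.full(jd.shape, low)
    if not ice_free:
        # retreat_jd == window end means ice never departs (perennial)
        in_season = (jd >= advance_jd) & ((jd < retreat_jd)
                                          | (retreat_jd >= end))
        sic[in_season] = plateau
        # internal ramps: ease in/out of the plateau without dipping below
        # the detection floor
        for k in range(ramp_days):
            frac = (k + 1) / (ramp_days + 1)
            lev = high_floor + frac * (plateau - high_floor)
            d_up = advance_jd + (ramp_days - 1 - k)
            d_dn = retreat_jd - 1 - (ramp_days - 1 - k)
            if advance_jd <= d_up < retreat_jd:
                sic[jd == d_up] = min(sic[jd == d_up][0], lev)
            if advance_jd <= d_dn < retreat_jd:
                sic[jd == d_dn] = min(sic[jd == d_dn][0], lev)

    if noise_sd > 0:
        rng = substream(seed, f"sic{anchor_year}")
        noise = np.clip(rng.normal(0, noise_sd, sic.shape),
                        -0.999 * margin, 0.999 * margin)
        sic = sic + noise
    sic = np.clip(sic, 0.0, 100.0)

    dates = window.dates()
    keep = np.ones(len(jd), dtype=bool)
    if cadence == "every-other-day":
        keep[1::2] = False
        # retain transition-adjacent days so interpolation is exact there
        if not ice_free:
            for d in (advance_jd - 1, advance_jd, retreat_jd - 1, retreat_jd):
                keep[(jd >= start) & (jd == d)] = True
        keep[0] = keep[-1] = True
    elif cadence != "daily":
        raise InvalidInputError(f"unknown cadence {cadence!r}")

    series = SeaIceSeries(dates[keep], sic[keep])
    # the truth the detectors should report, including sentinel semantics
    if ice_free:
        truth = {"year": anchor_year, "advance_jd": None, "retreat_jd": None,
                 "duration_days": 0}
    else:
        truth = {"year": anchor_year, "advance_jd": int(advance_jd),
                 "retreat_jd": int(retreat_jd),
                 "duration_days": int(retreat_jd - advance_jd)}
    return series, truth


def random_sic_truths(n: int, anchor_year: int, seed: int,
                      persistence: int = 5) -> list[tuple[int, int]]:
    """n random (advance, retreat) pairs inside the anchor year's window,
    each season at least ``persistence`` days long."""
    rng = substream(seed, "sic-truths")
    start, end = SearchWindow(anchor_year).start_jd, window_end_jd(anchor_year)
    out = []
    for _ in range(n):
        adv = int(rng.integers(start, end - persistence - 30))
        ret = int(rng.integers(adv + persistence, end))
        out.append((adv, ret))
    return out


# ---------------------------------------------------------------------------
# hydrographic profiles

def make_profile(mld_m: float,
                 step_kgm3: float,
                 gradient_below: float = 0.01,
                 noise_sd: float = 0.0,
                 dz: float = 2.0,
                 max_depth: float | None = None,
                 rho_surface: float = 1026.5,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two-layer density profile with a known mixed-layer base.

    Density is uniform (``rho_surface``) above ``mld_m``, jumps by
    ``step_kgm3`` across the interface, and increases at
    ``gradient_below`` kg m⁻³ m⁻¹ beneath it.  ``step_kgm3 = 0`` yields a
    (noisy) homogeneous profile with no resolvable mixed layer.

    Returns ``(depth, density, truth)`` with levels every ``dz`` metres
    down to ``max_depth`` (default: twice the interface depth, at least
    interface + 20 m, so the quality-index reference layer is resolved).
    """
    if mld_m <= 0 or dz <= 0:
        raise InvalidInputError("mld_m and dz must be positive")
    if max_depth is None:
        max_depth = max(2.0 * mld_m, mld_m + 20.0)
    depth = np.arange(dz, max_depth + dz / 2, dz)
    density = np.full(depth.shape, rho_surface)
    below = depth > mld_m
    density[below] = (rho_surface + step_kgm3
                      + gradient_below * (depth[below] - mld_m))
    if noise_sd > 0:
        rng = substream(seed, "profile")
        density = density + rng.normal(0, noise_sd, depth.shape)
    truth = {"mld_m": float(mld_m), "step_kgm3": float(step_kgm3),
             "dz": float(dz)}
    return depth, density, truth


# ---------------------------------------------------------------------------
# coupled regional fields

def _seasonal(doy: np.ndarray, peak_doy: float) -> np.ndarray:
    return np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)


def make_coupled_fields(rho_target: float = 0.70,
                        start: str = "2002-09-01",
                        end: str = "2018-08-31",
                        seasonal_frac: float = 0.25,
                        winter_months: tuple[int, ...] = (5, 6, 7, 8),
                        lat: np.ndarray | None = None,
                        lon: np.ndarray | None = None,
                        chla_mean_ugl: float = 0.70,
                        chla_log10_sd: float = 0.25,
                        sgmw_mean_pct: float = 2.6,
                        sgmw_sd_pct: float = 0.45,
                        sst_lead_days: float = 30.0,
                        cell_noise_sd: float = 0.01,
                        seed: int = 0,
                        ) -> tuple[dict[str, xr.DataArray], dict]:
    """Coupled daily gridded chl-a, sGMW, SST and SAT fields.

    The regional log10 chl-a and sGMW series share a standardized seasonal
    cycle peaking in mid-January (variance share ``seasonal_frac`` each)
    plus bivariate-normal anomalies whose correlation is chosen so the
    correlation of the *total* observed series equals ``rho_target``:
    with λ = √seasonal_frac, the anomaly correlation is
    (ρ_target − λ²)/(1 − λ²).  SST and SAT are seasonal sinusoids leading
    the meltwater cycle by ``sst_lead_days``.  Chl-a and sGMW are masked
    (NaN) during ``winter_months``, emulating missing winter ocean colour;
    SST/SAT have full coverage.

    The default span and winter gap leave ≈3.9k observed days, matching
    the order of the study's paired daily record.

    Returns ``(fields, truth)``: fields keyed ``chla`` (μg/l), ``sgmw``
    (%), ``sst``/``sat`` (°C); truth holds the generating parameters and
    the regional series before gridding.
    """
    if not -1.0 <= rho_target <= 1.0:
        raise InvalidInputError("rho_target must lie in [-1, 1]")
    lam2 = seasonal_frac
    if rho_target < lam2:
        raise InvalidInputError(
            "rho_target below the shared seasonal variance share; lower "
            "seasonal_frac")
    if lat is None:
        lat = np.arange(-69.0, -63.9, 1.0)
    if lon is None:
        lon = np.arange(-78.0, -65.9, 1.0)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)

    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    observed = ~dates.month.isin(winter_months)
    n_t = len(dates)

    # standardized shared seasonal signal over the *observed* days
    s_raw = _seasonal(doy, peak_doy=15.0)
    mu, sd = s_raw[observed].mean(), s_raw[observed].std()
    s = (s_raw - mu) / sd

    rng = substream(seed, "coupled")
    rho_e = (rho_target - lam2) / (1.0 - lam2)
    cov = np.array([[1.0, rho_e], [rho_e, 1.0]])
    e = rng.multivariate_normal([0.0, 0.0], cov, size=n_t)
    lam = np.sqrt(lam2)
    res = np.sqrt(1.0 - lam2)
    z_chla = lam * s + res * e[:, 0]
    z_sgmw = lam * s + res * e[:, 1]

    log10_chla = np.log10(chla_mean_ugl) + chla_log10_sd * z_chla
    chla = 10.0 ** log10_chla
    sgmw = np.clip(sgmw_mean_pct + sgmw_sd_pct * z_sgmw, 0.0, None)

    sst_season = _seasonal(doy, peak_doy=15.0 - sst_lead_days)
    sst = -0.5 + 3.0 * sst_season + 0.3 * rng.standard_normal(n_t)
    sat = -3.0 + 6.0 * sst_season + 1.0 * rng.standard_normal(n_t)

    def to_field(series: np.ndarray, mask_winter: bool) -> xr.DataArray:
        base = np.broadcast_to(series[:, None, None],
                               (n_t, lat.size, lon.size)).copy()
        if cell_noise_sd > 0:
            base += rng.normal(0, cell_noise_sd, base.shape)
        if mask_winter:
            base[~observed, :, :] = np.nan
        return xr.DataArray(base, dims=("time", "lat", "lon"),
                            coords={"time": dates, "lat": lat, "lon": lon})

    fields = {
        "chla": to_field(chla, True).assign_attrs(units="ug/l"),
        "sgmw": to_field(sgmw, True).assign_attrs(units="%"),
        "sst": to_field(sst, False).assign_attrs(units="degC"),
        "sat": to_field(sat, False).assign_attrs(units="degC"),
    }
    truth = {
        "rho_target": float(rho_target),
        "n_observed_days": int(observed.sum()),
        "regional": pd.DataFrame({"chla": chla, "sgmw": sgmw, "sst": sst,
                                  "sat": sat,
                                  "observed": observed}, index=dates),
    }
    return fields, truth
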