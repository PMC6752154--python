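"""Hargreaves reference evapotranspiration, climatic moisture deficit, and
bioclimatic summaries.

Daily reference evapotranspiration follows Hargreaves & Samani:

    ET0 = 0.0023 * Ra * (Tmean + 17.8) * sqrt(Tmax - Tmin)   [mm/day]

with Ra the extraterrestrial radiation in water-equivalent mm/day from
standard solar geometry (FAO-56 constants: solar constant 0.0820
MJ m-2 min-1, 0.408 mm per MJ m-2). The daily climatic moisture deficit is
max(0, ET0 - precipitation) and the annual CMD its sum over a calendar
year — the same quantity used to characterize both the test site weather
and the provenance-origin normals.

Anomaly integrals quantify extreme events: daily departures from a
day-of-year climatology are summed over a window, so the integral captures
both the size and the duration of an excursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
MJ_TO_MM = 0.408  # mm of evaporable water per MJ m-2

WEATHER_COLUMNS = ["date", "tmin", "tmax", "tmean", "precip"]


def extraterrestrial_radiation(latitude_deg: float, doy) -> np.ndarray:
    """Ra in water-equivalent mm/day for a latitude and day(s) of year.

    The sunset-hour-angle argument is clamped to [-1, 1], which handles
    polar day (Ra from a full diurnal arc) and polar night (Ra = 0)
    continuously.
    """
    doy = np.asarray(doy, dtype=float)
    phi = np.deg2rad(latitude_deg)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    cos_ws = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    ra_mj = (
        24.0 * 60.0 / np.pi
        * SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    return MJ_TO_MM * np.maximum(ra_mj, 0.0)


def hargreaves_et0(tmin, tmax, tmean, latitude_deg: float, doy) -> np.ndarray:
    """Hargreaves-Samani ET0 in mm/day; negative values clamped to 0.

    ``tmax < tmin`` raises; missing temperatures propagate as NaN so the
    caller can count and skip incomplete days.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    tmean = np.asarray(tmean, dtype=float)
    both = ~(np.isnan(tmin) | np.isnan(tmax))
    if np.any(tmax[both] < tmin[both]):
        raise ValueError("tmax < tmin encountered")
    ra = extraterrestrial_radiation(latitude_deg, doy)
    et0 = 0.0023 * ra * (tmean + 17.8) * np.sqrt(tmax - tmin)
    return np.where(np.isnan(et0), np.nan, np.maximum(et0, 0.0))


def _weather_frame(weather: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WEATHER_COLUMNS if c not in weather.columns]
    if missing:
        raise ValueError(f"weather table missing columns: {missing}")
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    both = w["tmin"].notna() & w["tmax"].notna()
    if (w.loc[both, "tmax"] < w.loc[both, "tmin"]).any():
        raise ValueError("tmax < tmin in weather record")
    if (w["precip"].dropna() < 0).any():
        raise ValueError("negative precipitation in weather record")
    return w


@dataclass
class DeficitSeries:
    """Daily ET0/deficit plus annual CMD with completeness accounting."""

    daily: pd.DataFrame  # date, et0, precip, deficit, complete (bool)
    annual: pd.DataFrame  # year, cmd, n_days, n_missing


def daily_deficit(weather: pd.DataFrame, latitude_deg: float) -> DeficitSeries:
    """Daily water deficit max(0, ET0 - precip) and annual CMD.

    Days with any missing input are excluded from the annual sums and
    counted in ``n_missing`` — no imputation.
    """
    w = _weather_frame(weather)
    doy = w["date"].dt.dayofyear.to_numpy()
    et0 = hargreaves_et0(
        w["tmin"].to_numpy(), w["tmax"].to_numpy(), w["tmean"].to_numpy(),
        latitude_deg, doy,
    )
    deficit = np.maximum(0.0, et0 - w["precip"].to_numpy(dtype=float))
    complete = ~np.isnan(deficit)
    daily = pd.DataFrame(
        {
            "date": w["date"],
            "et0": et0,
            "precip": w["precip"],
            "deficit": deficit,
            "complete": complete,
        }
    )
    g = daily.assign(year=daily["date"].dt.year).groupby("year")
    annual = g.agg(
        cmd=("deficit", lambda s: float(np.nansum(s))),
        n_days=("deficit", "size"),
        n_missing=("complete", lambda s: int((~s).sum())),
    ).reset_index()
    return DeficitSeries(daily=daily, annual=annual)


def day_of_year_climatology(
    dates: pd.Series,
    values: np.ndarray,
    reference_years: tuple[int, int] = (1961, 1990),
    smooth_days: int = 15,
) -> pd.Series:
    """Day-of-year normals over a reference period, circularly smoothed.

    Returns a Series indexed by day-of-year 1..366 (Feb 29 shares the
    day-366 slot's mean). A centred ``smooth_days`` circular running mean
    keeps anomaly baselines from inheriting day-to-day noise.
    """
    dates = pd.to_datetime(pd.Series(dates).reset_index(drop=True))
    vals = pd.Series(np.asarray(values, dtype=float))
    years = dates.dt.year
    mask = (years >= reference_years[0]) & (years <= reference_years[1]) & vals.notna()
    if not mask.any():
        raise ValueError(f"no data inside reference period {reference_years}")
    doy = dates.dt.dayofyear[mask]
    base = vals[mask].groupby(doy).mean()
    full = base.reindex(range(1, 367))
    if full.isna().any():
        # fill rare absent days (e.g. no leap year in reference) circularly
        full = full.ffill().bfill()
    arr = full.to_numpy()
    k = smooth_days
    if k > 1:
        ext = np.concatenate([arr[-(k // 2):], arr, arr[: k // 2]])
        arr = np.convolve(ext, np.ones(k) / k, mode="valid")
    return pd.Series(arr, index=range(1, 367), name="normal")


def anomaly_integral(
    dates: pd.Series,
    values: np.ndarray,
    climatology: pd.Series,
    window: tuple[str, str] | None = None,
) -> float:
    """Signed sum of daily departures from the climatology over a window.

    Sign is preserved: for a deficit series, positive integrals mean drier
    than normal. Missing days are dropped from the sum (the caller can
    compare ``completeness`` via :func:`window_completeness`).
    """
    dates = pd.to_datetime(pd.Series(dates).reset_index(drop=True))
    vals = pd.Series(np.asarray(values, dtype=float))
    if window is not None:
        lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        sel = (dates >= lo) & (dates <= hi)
        dates, vals = dates[sel], vals[sel]
    doy = dates.dt.dayofyear
    if not set(doy.unique()).issubset(set(climatology.index)):
        raise ValueError("climatology does not cover all days of year present")
    normals = climatology.reindex(doy).to_numpy()
    anom = vals.to_numpy() - normals
    return float(np.nansum(anom))


# ---------------------------------------------------------------------------
# Bioclimatic normals
# ---------------------------------------------------------------------------

#: The 13 climate-normal variables carried in provenance tables.
CLIMATE_NORMAL_VARIABLES = [
    "MAT", "MWMT", "MCMT", "TD", "MAP", "MSP", "PAS",
    "DD5", "DD_0", "FFP", "AHM", "SHM", "CMD",
]

_SUMMER_MONTHS = (5, 6, 7, 8, 9)  # May-September growing season


def derived_normals(monthly_tmean, monthly_precip) -> dict[str, float]:
    """Bioclimatic variables computable from 12 monthly normals.

    MAT (°C), MWMT/MCMT (warmest/coldest month Tmean, °C), continentality
    TD = MWMT - MCMT (°C), MAP (mm), May-September MSP (mm), annual
    heat-moisture AHM = (MAT + 10) / (MAP/1000) and summer heat-moisture
    SHM = MWMT / (MSP/1000).
    """
    t = np.asarray(monthly_tmean, dtype=float)
    p = np.asarray(monthly_precip, dtype=float)
    if t.shape != (12,) or p.shape != (12,):
        raise ValueError("need exactly 12 monthly values of tmean and precip")
    if np.any(np.isnan(t)) or np.any(np.isnan(p)):
        raise ValueError("missing month in monthly normals")
    mat = float(np.mean(t))
    mwmt = float(np.max(t))
    mcmt = float(np.min(t))
    map_ = float(np.sum(p))
    msp = float(np.sum(p[[m - 1 for m in _SUMMER_MONTHS]]))
    return {
        "MAT": mat,
        "MWMT": mwmt,
        "MCMT": mcmt,
        "TD": mwmt - mcmt,
        "MAP": map_,
        "MSP": msp,
        "AHM": (mat + 10.0) / (map_ / 1000.0),
        "SHM": mwmt / (msp / 1000.0),
    }


def read_climate_normals(path) -> pd.DataFrame:
    """Read a provenance climate-normal CSV and sanity-check invariants."""
    df = pd.read_csv(path, dtype={"provenance_id": str})
    missing = [c for c in CLIMATE_NORMAL_VARIABLES if c not in df.columns]
    if missing:
        raise ValueError(f"climate normals missing variables: {missing}")
    td_err = np.abs(df["TD"] - (df["MWMT"] - df["MCMT"]))
    if (td_err > 0.2).any():
        raise ValueError("TD inconsistent with MWMT - MCMT beyond rounding")
    if (df["MSP"] > df["MAP"] + 1e-9).any():
        raise ValueError("MSP exceeds MAP")
    return df
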