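"""Daily weather cleaning, gap filling and hourly interpolation.

Daily series are pandas DataFrames with columns ``date`` (datetime-like),
``tmin`` and ``tmax`` (°C, NaN = missing).  Hourly output carries a
``provenance`` flag so downstream users can see which values derive from
observations, auxiliary-station filling or interpolation.

Gap filling follows the bias-corrected auxiliary-station approach: for a
missing day, the mean difference between auxiliary and target station over
the shared non-missing days of a centred moving window (default 15 days) is
subtracted from the auxiliary observation.  tmin and tmax are filled
independently, each with its own bias estimate.

Daily-to-hourly conversion uses the idealized diurnal curve standard in
horticultural chill modelling: a sine rise from sunrise to the afternoon
peak and a logarithmic decline overnight, with sunrise and sunset from the
standard solar declination / hour-angle equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

_VARS = ("tmin", "tmax")


# ---------------------------------------------------------------------------
# Validation helpers


def _check_daily(df: pd.DataFrame, name: str = "series") -> pd.DataFrame:
    for col in ("date", "tmin", "tmax"):
        if col not in df.columns:
            raise ValueError(f"{name} lacks required column {col!r}")
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"])
    if not out["date"].is_monotonic_increasing or out["date"].duplicated().any():
        raise ValueError(f"{name} dates must be strictly increasing")
    both = out["tmin"].notna() & out["tmax"].notna()
    if (out.loc[both, "tmax"] < out.loc[both, "tmin"]).any():
        bad = out.loc[both & (out["tmax"] < out["tmin"]), "date"].iloc[0]
        raise ValueError(f"{name}: tmax < tmin on {bad.date()}")
    return out


# ---------------------------------------------------------------------------
# Bias-corrected gap filling


@dataclass(frozen=True)
class GapFillRecord:
    date: pd.Timestamp
    variable: str
    station_id: str | None
    bias: float | None
    bias_sd: float | None
    n_shared: int
    filled: bool
    flagged: bool


def fill_gaps_bias_corrected(
    target: pd.DataFrame,
    aux: pd.DataFrame,
    window_days: int = 15,
    flag_threshold: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill gaps in ``target`` from (possibly multiple) auxiliary stations.

    Returns the filled series and a QC report with one row per gap,
    recording the bias, its standard deviation over the window, the number
    of shared days and a flag when |bias| or its sd exceeds
    ``flag_threshold`` (°C).  Gaps with no shared day (or no auxiliary
    observation on the gap day) are left missing and flagged.  When ``aux``
    contains several stations, the one with the most shared days in the
    window is used, ties broken by smaller |bias|.
    """
    if window_days % 2 != 1:
        raise ValueError("window_days must be odd")
    half = window_days // 2
    tgt = _check_daily(target, "target").set_index("date")
    aux = aux.copy()
    if "station_id" not in aux.columns:
        aux["station_id"] = "aux"
    aux_by_station = {
        sid: _check_daily(g, f"aux[{sid}]").set_index("date")
        for sid, g in aux.groupby("station_id")
    }
    records: list[GapFillRecord] = []
    out = tgt.copy()
    for var in _VARS:
        for day in tgt.index[tgt[var].isna()]:
            lo, hi = day - pd.Timedelta(days=half), day + pd.Timedelta(days=half)
            window_target = tgt.loc[lo:hi, var]
            best: tuple[int, float, float, float, str] | None = None
            for sid, adf in aux_by_station.items():
                if day not in adf.index or pd.isna(adf.at[day, var]):
                    continue
                shared = window_target.dropna().index.intersection(
                    adf.loc[lo:hi, var].dropna().index)
                if len(shared) == 0:
                    continue
                diff = adf.loc[shared, var] - window_target.loc[shared]
                bias = float(diff.mean())
                sd = float(diff.std(ddof=1)) if len(shared) > 1 else 0.0
                key = (len(shared), -abs(bias))
                if best is None or key > (best[0], -abs(best[1])):
                    best = (len(shared), bias, sd, float(adf.at[day, var]), sid)
            if best is None:
                records.append(GapFillRecord(day, var, None, None, None, 0,
                                             filled=False, flagged=True))
                continue
            n_shared, bias, sd, aux_value, sid = best
            value = aux_value - bias
            out.at[day, var] = value
            records.append(GapFillRecord(
                day, var, sid, bias, sd, n_shared, filled=True,
                flagged=abs(bias) > flag_threshold or sd > flag_threshold))
    qc = pd.DataFrame([r.__dict__ for r in records],
                      columns=["date", "variable", "station_id", "bias",
                               "bias_sd", "n_shared", "filled", "flagged"])
    return out.reset_index(), qc


def interpolate_linear(series: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill interior gaps by linear interpolation in day index.

    Leading/trailing gaps remain missing and are listed in the returned
    report.  A series with no observations at all is unusable and raises.
    """
    df = _check_daily(series)
    if df[list(_VARS)].isna().all().all():
        raise ValueError("series has no tmin/tmax observations at all")
    report_rows = []
    for var in _VARS:
        col = df[var]
        interp = col.interpolate(method="linear", limit_area="inside")
        for day in df.loc[interp.isna(), "date"]:
            report_rows.append({"date": day, "variable": var,
                                "reason": "edge gap not interpolated"})
        df[var] = interp
    return df, pd.DataFrame(report_rows, columns=["date", "variable", "reason"])


# ---------------------------------------------------------------------------
# Solar geometry and the diurnal temperature curve


def solar_daylength(latitude: float, doy: int) -> tuple[float, float, float]:
    """(sunrise, sunset, daylength) in fractional hours of local solar time
    for the given latitude and day of year, from the standard declination /
    hour-angle equations.  Polar day/night is clamped."""
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    decl = math.radians(-23.44) * math.cos(2 * math.pi * (doy + 10) / 365.0)
    lat = math.radians(latitude)
    cos_h = -math.tan(lat) * math.tan(decl)
    cos_h = min(1.0, max(-1.0, cos_h))
    half = math.degrees(math.acos(cos_h)) / 15.0
    return 12.0 - half, 12.0 + half, 2.0 * half


def daily_to_hourly(series: pd.DataFrame, latitude: float) -> pd.DataFrame:
    """Convert a complete daily tmin/tmax series to hourly temperatures.

    Daytime follows a sine from tmin at sunrise to tmax at the afternoon
    peak (the hour nearest sunrise + (daylength + 4) / 2, anchored exactly
    at tmax so sampled series preserve the daily maximum), then declines
    along the sine to sunset and logarithmically overnight toward the next
    day's tmin at its sunrise.  Output has 24 rows per day with columns
    timestamp, temp, provenance.
    """
    df = _check_daily(series)
    missing = df.loc[df["tmin"].isna() | df["tmax"].isna(), "date"]
    if len(missing):
        raise ValueError(
            f"cannot build hourly series: missing tmin/tmax on {missing.iloc[0].date()}")
    dates = df["date"].dt.date.to_numpy()
    tmin = df["tmin"].to_numpy(float)
    tmax = df["tmax"].to_numpy(float)
    n = len(df)
    doys = df["date"].dt.dayofyear.to_numpy()
    sunrise = np.empty(n)
    sunset = np.empty(n)
    daylen = np.empty(n)
    for i in range(n):
        sunrise[i], sunset[i], daylen[i] = solar_daylength(latitude, int(doys[i]))

    def day_curve(i: int, t: float) -> float:
        """Sine section of day i evaluated at solar hour t (sunrise..sunset)."""
        peak = round(sunrise[i] + (daylen[i] + 4.0) / 2.0)
        if t <= peak:
            frac = (t - sunrise[i]) / max(peak - sunrise[i], 1e-9)
            return tmin[i] + (tmax[i] - tmin[i]) * math.sin(0.5 * math.pi * frac)
        span = max(sunset[i] + 4.0 - peak, 1e-9)
        frac = (t - peak) / span
        return tmin[i] + (tmax[i] - tmin[i]) * math.sin(
            0.5 * math.pi * (1.0 + frac))

    def sunset_temp(i: int) -> float:
        return day_curve(i, sunset[i])

    temps = np.empty(n * 24)
    for i in range(n):
        for h in range(24):
            idx = i * 24 + h
            if h < sunrise[i]:
                if i == 0:
                    temps[idx] = tmin[0]
                else:
                    ts = sunset_temp(i - 1)
                    night_len = 24.0 - sunset[i - 1] + sunrise[i]
                    elapsed = 24.0 - sunset[i - 1] + h
                    temps[idx] = ts - (ts - tmin[i]) * math.log1p(elapsed) \
                        / math.log1p(night_len)
            elif h <= sunset[i]:
                temps[idx] = day_curve(i, h)
            else:
                tmin_next = tmin[i + 1] if i + 1 < n else tmin[i]
                ts = sunset_temp(i)
                night_len = 24.0 - sunset[i] + (sunrise[i + 1] if i + 1 < n
                                                else sunrise[i])
                elapsed = h - sunset[i]
                temps[idx] = ts - (ts - tmin_next) * math.log1p(elapsed) \
                    / math.log1p(night_len)
        # anchor the sampled extremes exactly
        peak_h = int(round(sunrise[i] + (daylen[i] + 4.0) / 2.0))
        if 0 <= peak_h < 24:
            temps[i * 24 + peak_h] = tmax[i]
        rise_h = int(round(sunrise[i]))
        temps[i * 24 + rise_h] = tmin[i]

    timestamps = pd.date_range(pd.Timestamp(dates[0]), periods=n * 24,
                               freq="h")
    return pd.DataFrame({
        "timestamp": timestamps,
        "temp": temps,
        "provenance": "observed-derived",
    })


def hourly_to_array(hourly: pd.DataFrame) -> np.ndarray:
    """Temperature column of an hourly frame as a contiguous float array."""
    return hourly["temp"].to_numpy(float)
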