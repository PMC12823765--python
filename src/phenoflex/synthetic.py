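"""Synthetic weather and bloom-date generation with known ground truth.

The generator supports "virtual ecologist" calibration experiments: daily
Tmin/Tmax series are drawn from a sinusoidal annual cycle with AR(1)
weather noise, converted to hourly temperatures, and bloom dates are
simulated from a known parameter set plus integer-rounded Gaussian
observation noise.  Because the truth is known, parameter recovery and
end-to-end self-consistency can be tested without any real data.

The default recovery scenario mirrors a typical long-term orchard dataset:
one species, three cultivars and 25 seasons per cultivar at a mid-latitude
Mediterranean-temperate site, with 1-day observation noise.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import Observation
from .chill import IntermediateChillParams, NegationCycle, canonical_chill_params
from .engine import (SEASON_END, SEASON_START, SeasonSeries, season_bounds,
                     simulate_model)
from .params import CultivarRequirements, HeatSubmodelParams, ModelParams
from .weather import daily_to_hourly


@dataclass(frozen=True)
class WeatherGenConfig:
    """Synthetic daily-weather settings.

    The daily mean follows ``annual_mean - annual_amplitude *
    cos(2*pi*(doy - coldest_doy)/365)`` plus AR(1) noise (lag-1 coefficient
    ``ar1``, innovation standard deviation ``noise_sd``); tmin/tmax sit a
    half diurnal range below/above the mean.  Coldest day defaults to
    mid-January (Northern Hemisphere).
    """

    latitude: float = 40.0
    first_year: int = 1995
    years: int = 26
    annual_mean: float = 14.0
    annual_amplitude: float = 9.0
    diurnal_range: float = 10.0
    ar1: float = 0.7
    noise_sd: float = 2.0
    coldest_doy: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diurnal_range <= 0:
            raise ValueError("diurnal range must be positive")
        if not -90 <= self.latitude <= 90:
            raise ValueError("invalid latitude")
        if not 0 <= self.ar1 < 1:
            raise ValueError("AR(1) coefficient must be in [0, 1)")


@dataclass(frozen=True)
class TruthSpec:
    """Ground-truth model: species-shared submodels (intermediate chill
    form) plus per-cultivar requirements and bloom-observation noise."""

    shared_chill: IntermediateChillParams = field(
        default_factory=lambda: IntermediateChillParams(
            theta_c=286.5, tau=30.0, pie_c=38.0))
    Tf: float = 4.0
    slope: float = 1.6
    heat: HeatSubmodelParams = field(
        default_factory=lambda: HeatSubmodelParams(Tb=4.0, Tu=25.0))
    cultivars: dict[str, CultivarRequirements] = field(
        default_factory=lambda: {
            "early": CultivarRequirements(yc=24.0, zc=190.0, s1=0.4),
            "mid": CultivarRequirements(yc=32.0, zc=260.0, s1=0.6),
            "late": CultivarRequirements(yc=40.0, zc=340.0, s1=0.9),
        })
    obs_noise_sd: float = 1.0
    cycle: NegationCycle = field(default_factory=NegationCycle)

    def model_for(self, cultivar: str) -> ModelParams:
        chill = canonical_chill_params(self.shared_chill, Tf=self.Tf,
                                       slope=self.slope, cycle=self.cycle)
        return ModelParams(chill=chill, heat=self.heat,
                           req=self.cultivars[cultivar])


def generate_weather(config: WeatherGenConfig) -> pd.DataFrame:
    """Daily tmin/tmax series covering whole calendar years, reproducible
    from the config seed."""
    start = dt.date(config.first_year, 1, 1)
    end = dt.date(config.first_year + config.years - 1, 12, 31)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy()
    mean = config.annual_mean - config.annual_amplitude * np.cos(
        2 * np.pi * (doy - config.coldest_doy) / 365.0)
    rng = np.random.default_rng(config.seed)
    eps = rng.normal(0.0, config.noise_sd, size=len(dates))
    noise = np.empty(len(dates))
    acc = 0.0
    for i in range(len(dates)):
        acc = config.ar1 * acc + eps[i]
        noise[i] = acc
    mean = mean + noise
    half = config.diurnal_range / 2.0
    return pd.DataFrame({
        "station_id": "synthetic",
        "date": dates,
        "tmin": mean - half,
        "tmax": mean + half,
    })


def seasons_from_weather(
    weather: pd.DataFrame,
    latitude: float,
    start: tuple[int, int] = SEASON_START,
    end: tuple[int, int] = SEASON_END,
) -> dict[int, SeasonSeries]:
    """Cut a daily weather frame into hourly dormancy-season series, one
    per fully covered harvest year."""
    hourly = daily_to_hourly(weather[["date", "tmin", "tmax"]], latitude)
    hourly = hourly.set_index("timestamp")
    first = pd.Timestamp(weather["date"].min())
    last = pd.Timestamp(weather["date"].max())
    out: dict[int, SeasonSeries] = {}
    for year in range(first.year, last.year + 2):
        d0, d1 = season_bounds(year, start, end)
        if pd.Timestamp(d0) < first or pd.Timestamp(d1) > last:
            continue
        chunk = hourly.loc[pd.Timestamp(d0):
                           pd.Timestamp(d1) + pd.Timedelta(hours=23), "temp"]
        out[year] = SeasonSeries(season=year, start_date=d0,
                                 temps_c=chunk.to_numpy())
    return out


def generate_bloom_observations(
    seasons: dict[int, SeasonSeries],
    truth: TruthSpec,
    seed: int = 0,
    location: str = "synthetic",
) -> pd.DataFrame:
    """Phenology table (location, species, cultivar, season, bloom_date,
    bloom_doy, status) simulated under the truth, with integer-rounded
    Gaussian observation noise on the bloom day.  Seasons that fail to
    bloom are emitted with status ``no_bloom`` and empty date."""
    rng = np.random.default_rng(seed)
    rows = []
    for cultivar in sorted(truth.cultivars):
        model = truth.model_for(cultivar)
        for year in sorted(seasons):
            pred = simulate_model(seasons[year], model)
            if not pred.bloomed:
                rows.append({"location": location, "species": "synthetic",
                             "cultivar": cultivar, "season": year,
                             "bloom_date": None, "bloom_doy": None,
                             "status": "no_bloom"})
                continue
            doy = pred.bloom_doy
            if truth.obs_noise_sd > 0:
                doy = int(round(doy + rng.normal(0.0, truth.obs_noise_sd)))
            date = dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)
            rows.append({"location": location, "species": "synthetic",
                         "cultivar": cultivar, "season": year,
                         "bloom_date": date.isoformat(), "bloom_doy": doy,
                         "status": "bloom"})
    return pd.DataFrame(rows)


def observations_for_calibration(
    phenology: pd.DataFrame,
    seasons: dict[int, SeasonSeries],
) -> list[Observation]:
    """Join a phenology table with matching season series, dropping
    no-bloom records and seasons without weather coverage."""
    out = []
    for _, row in phenology.iterrows():
        if row.get("status", "bloom") != "bloom":
            continue
        year = int(row["season"])
        if year not in seasons:
            continue
        out.append(Observation(cultivar=str(row["cultivar"]), season=year,
                               observed_doy=float(row["bloom_doy"]),
                               series=seasons[year]))
    return out
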