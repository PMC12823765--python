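"""Season simulator coupling the chill and heat submodels.

A dormancy season runs from 1 September of the year before harvest through
30 June of the harvest year (configurable).  Chill accumulates hour by
hour; the potential for heat accumulation is gated by a logistic function
of accumulated chill centred on the cultivar's chill requirement yc with
slope s1.  Heat is counted in normalized GDH units (the hourly response
divided by its maximum Tu - Tb, i.e. "effective optimal hours"), which is
the unit in which the heat requirement zc is expressed.  Bloom is the
calendar day of the first hour at which gated heat reaches zc; if the
season ends first, the model records a failure to bloom.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import KELVIN_OFFSET
from .params import (ChillSubmodelParams, CultivarRequirements,
                     HeatSubmodelParams, ModelParams)

#: Default dormancy-season window: (start month, start day) in the year
#: before harvest through (end month, end day) of the harvest year.
SEASON_START = (9, 1)
SEASON_END = (6, 30)


def season_bounds(season: int,
                  start: tuple[int, int] = SEASON_START,
                  end: tuple[int, int] = SEASON_END) -> tuple[dt.date, dt.date]:
    """Inclusive calendar bounds of the dormancy season labelled by its
    harvest year."""
    return (dt.date(season - 1, *start), dt.date(season, *end))


def date_to_doy(date: dt.date, season: int) -> int:
    """Day-of-year in the harvest-year convention: 1 = 1 January of the
    harvest year; dates in the preceding autumn get zero/negative values."""
    return (date - dt.date(season, 1, 1)).days + 1


def doy_to_date(doy: int, season: int) -> dt.date:
    return dt.date(season, 1, 1) + dt.timedelta(days=doy - 1)


@dataclass(frozen=True)
class SeasonSeries:
    """One dormancy season's contiguous hourly temperatures.

    ``temps_c[i]`` is the temperature for hour i counted from 00:00 on
    ``start_date``; the series must cover whole days.
    """

    season: int
    start_date: dt.date
    temps_c: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temps_c, dtype=np.float64)
        object.__setattr__(self, "temps_c", t)
        if t.ndim != 1 or t.size % 24 != 0:
            raise ValueError("hourly series must cover whole days")
        if not np.all(np.isfinite(t)):
            raise ValueError("season series contains missing temperatures")

    @property
    def n_days(self) -> int:
        return self.temps_c.size // 24

    @property
    def start_doy(self) -> int:
        return date_to_doy(self.start_date, self.season)

    @property
    def end_doy(self) -> int:
        return self.start_doy + self.n_days - 1

    def date_of_hour(self, hour: int) -> dt.date:
        return self.start_date + dt.timedelta(days=hour // 24)


@dataclass(frozen=True)
class BloomPrediction:
    season: int
    status: str  # "bloom" | "no_bloom"
    bloom_date: dt.date | None = None
    bloom_doy: int | None = None
    chill_trace: np.ndarray | None = field(default=None, repr=False)
    heat_trace: np.ndarray | None = field(default=None, repr=False)

    @property
    def bloomed(self) -> bool:
        return self.status == "bloom"


def heat_effectiveness(y: float, req: CultivarRequirements) -> float:
    """Logistic gate on heat accumulation: 0.5 when accumulated chill y
    equals the chill requirement yc, approaching 1 beyond it; s1 sets how
    sharply the transition from chill to heat accumulation occurs."""
    return 1.0 / (1.0 + math.exp(-req.s1 * (y - req.yc)))


def simulate_season(season: SeasonSeries, chill: ChillSubmodelParams,
                    heat: HeatSubmodelParams, req: CultivarRequirements,
                    traces: bool = False) -> BloomPrediction:
    """Predict bloom (or failure to bloom) for one season."""
    if season.n_days < 30:
        raise ValueError(
            f"season window of {season.n_days} days is degenerate (< 30)")
    args = (season.temps_c, chill.E0, chill.E1, chill.A0, chill.A1,
            chill.Tf + KELVIN_OFFSET, chill.slope,
            heat.Tb, heat.Tu, heat.Tc, req.yc, req.zc, req.s1)
    y_tr = z_tr = None
    if traces:
        y_tr, z_tr = _kernels.chill_heat_traces(*args)
        hits = np.nonzero(z_tr >= req.zc)[0]
        hour = int(hits[0]) if hits.size else -1
    else:
        hour = int(_kernels.bloom_hour(*args))
    if hour < 0:
        return BloomPrediction(season=season.season, status="no_bloom",
                               chill_trace=y_tr, heat_trace=z_tr)
    date = season.date_of_hour(hour)
    return BloomPrediction(
        season=season.season, status="bloom", bloom_date=date,
        bloom_doy=date_to_doy(date, season.season),
        chill_trace=y_tr, heat_trace=z_tr,
    )


def simulate_model(season: SeasonSeries, params: ModelParams,
                   traces: bool = False) -> BloomPrediction:
    return simulate_season(season, params.chill, params.heat, params.req,
                           traces=traces)


#: Diagnostic grid: -5.0, -4.9, ..., 50.0 °C (551 points).
RESPONSE_GRID = np.round(np.arange(-50, 501) * 0.1, 1)
RESPONSE_HOURS = 1200


def temperature_response_curves(
    chill: ChillSubmodelParams, heat: HeatSubmodelParams,
    hours: int = RESPONSE_HOURS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chill and heat responses to long constant-temperature exposure.

    For every grid temperature the submodels are run for ``hours`` hours at
    that constant temperature.  Returns (grid °C, chill portions, heat
    response normalized to a maximum of 1.0)."""
    grid = RESPONSE_GRID
    chill_resp = np.empty(grid.size)
    heat_resp = np.empty(grid.size)
    tf_k = chill.Tf + KELVIN_OFFSET
    for i, t in enumerate(grid):
        temps_k = np.full(hours, t + KELVIN_OFFSET)
        chill_resp[i] = _kernels.chill_trajectory(
            temps_k, chill.E0, chill.E1, chill.A0, chill.A1,
            tf_k, chill.slope)[-1]
        heat_resp[i] = hours * _kernels._gdh(float(t), heat.Tb, heat.Tu,
                                             heat.Tc)
    peak = heat_resp.max()
    if peak > 0:
        heat_resp = heat_resp / peak
    return grid, chill_resp, heat_resp
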