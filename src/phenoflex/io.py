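"""Readers and writers for the pipeline's text formats.

Formats: phenology CSV (location, species, cultivar, season, bloom_date),
daily weather CSV (station_id, date, tmin, tmax; empty cell = missing),
hourly weather CSV (station_id, timestamp, temp, provenance), fitted-model
JSON, metrics CSV and response-curve CSV.  Dates are ISO-8601 everywhere;
day-of-year values are derived, never stored as primary data.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CONSTANTS, FittedModel
from .engine import date_to_doy
from .params import params_to_dict

PHENOLOGY_COLUMNS = ("location", "cultivar", "season", "bloom_date")


@dataclass(frozen=True)
class PhenologyRecord:
    location: str
    cultivar: str
    season: int
    bloom_date: dt.date
    species: str = ""

    @property
    def bloom_doy(self) -> int:
        return date_to_doy(self.bloom_date, self.season)


class PhenologyFormatError(ValueError):
    """Raised when a phenology file cannot be used; carries row-level
    problems."""

    def __init__(self, message: str, problems: list[str] | None = None):
        super().__init__(message)
        self.problems = problems or []


def read_phenology(path: str | Path,
                   strict: bool = True) -> tuple[list[PhenologyRecord], list[str]]:
    """Parse and validate a phenology CSV.

    Returns (records, problems).  Malformed rows are collected with line
    numbers; with ``strict`` (default) any problem, including duplicate
    (cultivar, season, location) keys, raises :class:`PhenologyFormatError`.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in PHENOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise PhenologyFormatError(f"{path}: missing required columns {missing}")
    records: list[PhenologyRecord] = []
    problems: list[str] = []
    seen: dict[tuple, int] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            season = int(row["season"])
            date = dt.date.fromisoformat(str(row["bloom_date"]))
        except (TypeError, ValueError) as exc:
            problems.append(f"line {line}: {exc}")
            continue
        if not 1 <= date.month <= 6:
            problems.append(
                f"line {line}: bloom date {date} outside January-June")
            continue
        key = (row["cultivar"], season, row["location"])
        if key in seen:
            problems.append(
                f"line {line}: duplicate (cultivar, season, location) "
                f"{key} first seen on line {seen[key]}")
            continue
        seen[key] = line
        records.append(PhenologyRecord(
            location=str(row["location"]), cultivar=str(row["cultivar"]),
            season=season, bloom_date=date,
            species=str(row["species"]) if "species" in df.columns else ""))
    if strict and problems:
        raise PhenologyFormatError(
            f"{path}: {len(problems)} malformed rows", problems)
    return records, problems


def write_phenology(records: list[PhenologyRecord], path: str | Path) -> None:
    pd.DataFrame([{
        "location": r.location, "species": r.species, "cultivar": r.cultivar,
        "season": r.season, "bloom_date": r.bloom_date.isoformat(),
    } for r in records]).to_csv(path, index=False)


def read_daily_weather(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("station_id", "date", "tmin", "tmax"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing weather column {col!r}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_daily_weather(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out.to_csv(path, index=False)


def write_hourly_weather(df: pd.DataFrame, path: str | Path,
                         station_id: str = "station") -> None:
    out = df.copy()
    if "station_id" not in out.columns:
        out.insert(0, "station_id", station_id)
    out.to_csv(path, index=False)


def read_hourly_weather(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


# ---------------------------------------------------------------------------
# Fitted models and run manifests


def fitted_model_to_dict(fit: FittedModel) -> dict:
    return {
        "scheme": fit.scheme,
        "species": fit.species,
        "constants": CONSTANTS,
        "shared_intermediate": fit.shared_intermediate,
        "cultivars": {c: params_to_dict(p) for c, p in fit.params.items()},
        "vector": [float(v) for v in fit.vector],
        "layout": list(fit.layout.names),
        "objective": fit.objective,
        "seed": fit.seed,
        "converged": fit.converged,
    }


def save_fitted_model(fit: FittedModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fitted_model_to_dict(fit), indent=2,
                                     sort_keys=True))


def write_metrics(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def write_response_curves(grid: np.ndarray, chill_resp: np.ndarray,
                          heat_resp: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({
        "temperature": grid,
        "chill_response": chill_resp,
        "heat_response_normalized": heat_resp,
    }).to_csv(path, index=False)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path: str | Path, stages: list[str], config: dict,
                   seed: int) -> None:
    from . import __version__

    Path(path).write_text(json.dumps({
        "package_version": __version__,
        "stages": stages,
        "seed": seed,
        "config_hash": config_hash(config),
    }, indent=2, sort_keys=True))
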