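"""End-to-end pipeline: weather -> seasons -> calibration -> evaluation.

Driven by a plain dictionary (usually parsed from a YAML config).  The
pipeline is deterministic given the config and its seeds, and writes a
manifest recording the package version, seed and a config hash.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path

import pandas as pd

from . import io as pfio
from .calibration import (CalibrationProblem, FittedModel, Observation,
                          OptimizerBudget, calibrate, default_bounds)
from .engine import SEASON_END, SEASON_START, simulate_model
from .evaluation import SplitSpec, compute_metrics, split
from .synthetic import (TruthSpec, WeatherGenConfig,
                        generate_bloom_observations, generate_weather,
                        observations_for_calibration, seasons_from_weather)

log = logging.getLogger("phenoflex")


def observations_from_files(weather: pd.DataFrame, records,
                            latitude: float,
                            start=SEASON_START, end=SEASON_END
                            ) -> list[Observation]:
    """Match phenology records to hourly season series built from a daily
    weather frame; records without complete weather coverage are dropped
    with a warning."""
    seasons = seasons_from_weather(weather, latitude, start, end)
    out: list[Observation] = []
    for r in records:
        if r.season not in seasons:
            log.warning("[match] dropping %s season %s: no complete weather",
                        r.cultivar, r.season)
            continue
        out.append(Observation(cultivar=r.cultivar, season=r.season,
                               observed_doy=float(r.bloom_doy),
                               series=seasons[r.season]))
    return out


def budget_from_config(cfg: dict) -> OptimizerBudget:
    return OptimizerBudget(**cfg) if cfg else OptimizerBudget()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run simulate (optional) -> calibrate -> evaluate and write the
    artifact bundle.  Returns a summary dict with file paths and headline
    metrics."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages: list[str] = []
    scheme = config.get("scheme", "combined_fit")
    if scheme not in ("baseline", "cultivar_fit", "combined_fit"):
        raise ValueError(f"config: unknown scheme {scheme!r}")
    latitude = float(config.get("latitude", 40.0))

    if config.get("synthetic", False):
        log.info("[simulate] generating synthetic weather and bloom dates")
        wcfg = WeatherGenConfig(latitude=latitude, seed=seed,
                                **config.get("weather_gen", {}))
        weather = generate_weather(wcfg)
        seasons = seasons_from_weather(weather, latitude)
        truth = TruthSpec()
        phen = generate_bloom_observations(seasons, truth, seed=seed)
        pfio.write_daily_weather(weather, out / "weather.csv")
        phen.to_csv(out / "phenology.csv", index=False)
        observations = observations_for_calibration(phen, seasons)
        stages.append("simulate")
    else:
        weather = pfio.read_daily_weather(config["weather"])
        records, _ = pfio.read_phenology(config["phenology"])
        observations = observations_from_files(weather, records, latitude)

    split_cfg = config.get("split", {})
    spec = SplitSpec(mode=split_cfg.get("mode", "full"),
                     seed=int(split_cfg.get("seed", seed)))
    cal, val, excluded = split(observations, spec)
    if excluded:
        log.warning("[split] excluded %d observations of under-sampled "
                    "cultivars", len(excluded))

    log.info("[calibrate] scheme=%s n_cal=%d seed=%d", scheme, len(cal), seed)
    bounds = default_bounds()
    bounds.update({k: tuple(v) for k, v in config.get("bounds", {}).items()})
    problem = CalibrationProblem(
        scheme=scheme, observations=tuple(cal), bounds=bounds,
        budget=budget_from_config(config.get("budget", {})), seed=seed,
        species=config.get("species", "species"))
    fit = calibrate(problem)
    pfio.save_fitted_model(fit, out / "fitted_model.json")
    stages.append("calibrate")

    log.info("[evaluate] computing metrics on calibration and validation")
    metric_rows = []
    pred_rows = []
    for subset, data in (("cal", cal), ("val", val)):
        by_cultivar: dict[str, list] = {}
        for o in data:
            by_cultivar.setdefault(o.cultivar, []).append(o)
        for cultivar, group in sorted(by_cultivar.items()):
            pred, obsv = [], []
            n_no_bloom = 0
            for o in group:
                p = simulate_model(o.series, fit.params[cultivar])
                pred_rows.append({
                    "season": o.season, "cultivar": cultivar,
                    "subset": subset, "status": p.status,
                    "bloom_date": p.bloom_date.isoformat() if p.bloomed else "",
                    "bloom_doy": p.bloom_doy if p.bloomed else "",
                })
                if p.bloomed:
                    pred.append(p.bloom_doy)
                    obsv.append(o.observed_doy)
                else:
                    n_no_bloom += 1
            if len(pred) >= 2:
                report = compute_metrics(pred, obsv).as_dict()
            else:
                report = {}
            metric_rows.append({"species": problem.species,
                                "cultivar": cultivar, "scheme": scheme,
                                "split": spec.mode, "subset": subset,
                                "n_no_bloom": n_no_bloom, **report})
    pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False)
    pfio.write_metrics(metric_rows, out / "metrics.csv")
    stages.append("evaluate")

    from .engine import temperature_response_curves

    any_params = fit.params[sorted(fit.params)[0]]
    grid, chill_resp, heat_resp = temperature_response_curves(
        any_params.chill, any_params.heat)
    pfio.write_response_curves(grid, chill_resp, heat_resp,
                               out / "response_curves.csv")
    pfio.write_manifest(out / "manifest.json", stages, config, seed)
    return {
        "out_dir": str(out),
        "stages": stages,
        "objective": fit.objective,
        "metrics": metric_rows,
    }
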