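"""Data splitting and bloom-prediction performance metrics.

Metrics follow standard phenology-model validation practice: RMSE (days),
RPIQ (interquartile range of the observations divided by RMSE; quartiles by
linear interpolation between order statistics), mean bias (predicted minus
observed, days) and the proportion of large errors (|residual| > 7 days).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class SplitSpec:
    """Calibration/validation split specification.

    ``full`` mode assigns round(0.75 * n) observations per cultivar to
    calibration (round-half-to-even); ``scarce`` mode assigns exactly 10.
    """

    mode: str = "full"
    calibration_fraction: float = 0.75
    scarce_count: int = 10
    seed: int = 0
    chronological: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("full", "scarce"):
            raise ValueError(f"unknown split mode {self.mode!r}")

    def n_calibration(self, n: int) -> int:
        if self.mode == "scarce":
            return self.scarce_count
        return round(self.calibration_fraction * n)

    def min_observations(self) -> int:
        # scarce needs >= 11 so at least one validation point remains
        return self.scarce_count + 1 if self.mode == "scarce" else 2


def split(
    observations: Sequence,
    spec: SplitSpec,
    cultivar_of=lambda obs: obs.cultivar,
    sort_key=lambda obs: obs.season,
) -> tuple[list, list, list]:
    """Partition observations per cultivar into calibration and validation.

    Returns (calibration, validation, excluded) where ``excluded`` holds
    observations of cultivars with too few records for the requested mode.
    The partition is random per cultivar (chronological behind a flag),
    deterministic in the seed, disjoint and exhaustive.
    """
    by_cultivar: dict[Hashable, list] = {}
    for obs in observations:
        by_cultivar.setdefault(cultivar_of(obs), []).append(obs)
    rng = np.random.default_rng(spec.seed)
    cal: list = []
    val: list = []
    excluded: list = []
    for cultivar in sorted(by_cultivar, key=str):
        group = sorted(by_cultivar[cultivar], key=sort_key)
        if len(group) < spec.min_observations():
            excluded.extend(group)
            continue
        n_cal = spec.n_calibration(len(group))
        if spec.chronological:
            idx = np.arange(len(group))
        else:
            idx = rng.permutation(len(group))
        cal.extend(group[i] for i in idx[:n_cal])
        val.extend(group[i] for i in idx[n_cal:])
    return cal, val, excluded


@dataclass(frozen=True)
class MetricReport:
    rmse: float
    rpiq: float | None  # None flags an infinite ratio (rmse == 0)
    mean_bias: float
    n: int
    prop_large_error: float  # share of |residual| > 7 days

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "rpiq": self.rpiq if self.rpiq is not None else math.inf,
            "mean_bias": self.mean_bias,
            "n": self.n,
            "prop_large_error": self.prop_large_error,
        }


LARGE_ERROR_DAYS = 7.0


def compute_metrics(predicted: Iterable[float],
                    observed: Iterable[float]) -> MetricReport:
    """RMSE / RPIQ / mean bias / large-error share for paired bloom DOYs."""
    pred = np.asarray(list(predicted), dtype=float)
    obs = np.asarray(list(observed), dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(
            f"length mismatch: {pred.size} predictions vs {obs.size} observations")
    if pred.size < 2:
        raise ValueError("need at least 2 paired values (IQR requires spread)")
    res = pred - obs
    rmse = float(np.sqrt(np.mean(res ** 2)))
    q1, q3 = np.percentile(obs, [25, 75])  # linear interpolation
    rpiq = float((q3 - q1) / rmse) if rmse > 0 else None
    return MetricReport(
        rmse=rmse,
        rpiq=rpiq,
        mean_bias=float(np.mean(res)),
        n=int(pred.size),
        prop_large_error=float(np.mean(np.abs(res) > LARGE_ERROR_DAYS)),
    )
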