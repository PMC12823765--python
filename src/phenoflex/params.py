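"""Parameter containers for the chill and heat submodels and per-cultivar
bloom requirements, plus their JSON serialization.

Two equivalent parameterizations of the Dynamic Model's kinetics are
supported: the *canonical* set (E0, E1, A0, A1, Tf, slope) used when running
the model, and the *intermediate* set (theta_star, theta_c, tau, pie_c)
used during calibration because its components have narrow, interpretable
bounds.  Conversion between the two lives in :mod:`phenoflex.chill`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path

from .constants import THETA_STAR, TC_HEAT


@dataclass(frozen=True)
class ChillSubmodelParams:
    """Canonical Dynamic Model parameters.

    E0/E1 are activation energies (K) for forming/destroying the precursor
    of the dormancy-breaking factor (PDBF); A0/A1 (1/h) the corresponding
    amplitudes; Tf (°C) and slope control the sigmoidal conversion of PDBF
    to its irreversible form.
    """

    E0: float = 3372.8
    E1: float = 9900.3
    A0: float = 6319.5
    A1: float = 5.939917e13
    Tf: float = 4.0
    slope: float = 1.6

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.E0, self.E1, self.A0, self.A1,
                                       self.Tf, self.slope))):
            raise ValueError("chill parameters must be finite")
        if self.A0 <= 0 or self.A1 <= 0:
            raise ValueError("amplitudes A0, A1 must be positive")
        if self.E1 <= self.E0:
            raise ValueError("destruction energy E1 must exceed E0")
        if self.slope <= 0:
            raise ValueError("conversion slope must be positive")


@dataclass(frozen=True)
class IntermediateChillParams:
    """Interpretable reparameterization of the Dynamic Model kinetics.

    theta_star: optimal constant temperature for chill accumulation (K),
    fixed at 279 K.  theta_c: critical constant temperature (K) at and
    above which no chill portions accumulate.  tau: hours needed to deliver
    the first chill portion at constant theta_star.  pie_c: critical period
    (h) of a combined cool/warm temperature cycle at which chill negation
    sets in.
    """

    theta_c: float
    tau: float
    pie_c: float
    theta_star: float = THETA_STAR

    def __post_init__(self) -> None:
        if self.theta_star >= self.theta_c:
            raise ValueError("theta_star must lie below theta_c")
        if self.tau <= 0 or self.pie_c <= 0:
            raise ValueError("tau and pie_c must be positive")


@dataclass(frozen=True)
class HeatSubmodelParams:
    """Growing Degree Hours cardinal temperatures (°C): base Tb, optimum
    Tu, critical Tc (fixed at 36 °C throughout calibration)."""

    Tb: float = 4.0
    Tu: float = 26.0
    Tc: float = TC_HEAT

    def __post_init__(self) -> None:
        if not (self.Tb < self.Tu < self.Tc):
            raise ValueError("require Tb < Tu < Tc")


@dataclass(frozen=True)
class CultivarRequirements:
    """Per-cultivar bloom requirements: chill requirement yc (chill-portion
    variant), heat requirement zc (normalized GDH variant) and transition
    slope s1 (dimensionless; large -> sequential chill-then-heat)."""

    yc: float
    zc: float
    s1: float

    def __post_init__(self) -> None:
        if self.yc <= 0 or self.zc <= 0 or self.s1 <= 0:
            raise ValueError("yc, zc and s1 must be positive")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set needed to simulate one cultivar's bloom."""

    chill: ChillSubmodelParams = field(default_factory=ChillSubmodelParams)
    heat: HeatSubmodelParams = field(default_factory=HeatSubmodelParams)
    req: CultivarRequirements = field(
        default_factory=lambda: CultivarRequirements(yc=40.0, zc=300.0, s1=0.5)
    )


# ---------------------------------------------------------------------------
# JSON round-trip


def params_to_dict(p: ModelParams) -> dict:
    return {
        "parameterization": "canonical",
        "chill": asdict(p.chill),
        "heat": asdict(p.heat),
        "requirements": asdict(p.req),
    }


def params_from_dict(d: dict) -> ModelParams:
    tag = d.get("parameterization", "canonical")
    if tag == "canonical":
        chill = ChillSubmodelParams(**d["chill"])
    elif tag == "intermediate":
        from .chill import intermediate_to_canonical

        ip = IntermediateChillParams(
            theta_c=d["chill"]["theta_c"],
            tau=d["chill"]["tau"],
            pie_c=d["chill"]["pie_c"],
            theta_star=d["chill"].get("theta_star", THETA_STAR),
        )
        E0, E1, A0, A1 = intermediate_to_canonical(ip)
        chill = ChillSubmodelParams(E0=E0, E1=E1, A0=A0, A1=A1,
                                    Tf=d["chill"]["Tf"],
                                    slope=d["chill"]["slope"])
    else:
        raise ValueError(f"unknown parameterization tag {tag!r}")
    return ModelParams(
        chill=chill,
        heat=HeatSubmodelParams(**d["heat"]),
        req=CultivarRequirements(**d["requirements"]),
    )


def save_params(p: ModelParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params_to_dict(p), indent=2))


def load_params(path: str | Path) -> ModelParams:
    return params_from_dict(json.loads(Path(path).read_text()))
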