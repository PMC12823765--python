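"""Dynamic Model chill accumulation and the intermediate-parameter
reparameterization.

The Dynamic Model describes winter chill as two-step kinetics: a precursor
of the dormancy-breaking factor (PDBF, level ``x``) forms and decays with
temperature-dependent Arrhenius rates; each time ``x`` reaches 1 a
temperature-dependent fraction is converted irreversibly into accumulated
chill (``y``, measured in Chill Portions).

Because the canonical kinetic constants (E0, E1, A0, A1) are poorly
constrained and span many orders of magnitude, calibration instead searches
over four *intermediate* parameters with narrow, interpretable ranges:

* ``theta_star`` — the optimal constant chilling temperature (K; fixed at
  279 K, i.e. 6 °C);
* ``theta_c`` — the critical constant temperature at and above which no
  chill accumulates (equivalently, the steady-state precursor level at
  ``theta_c`` equals 1);
* ``tau`` — the time (h) needed to deliver the first chill portion at a
  constant ``theta_star``;
* ``pie_c`` — the critical period (h) of a combined cool/warm temperature
  cycle at which chill negation sets in.

:func:`intermediate_to_canonical` inverts these defining conditions
numerically (root-finding rather than a transcribed closed form), and the
test suite verifies the conditions by direct simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .constants import KELVIN_OFFSET, THETA_STAR
from .params import ChillSubmodelParams, IntermediateChillParams


@dataclass(frozen=True)
class ChillState:
    """Precursor level x (dimensionless) and accumulated chill y (Chill
    Portions)."""

    x: float = 0.0
    y: float = 0.0


def conversion_fraction(temp_k: float, params: ChillSubmodelParams) -> float:
    """Sigmoidal fraction of the precursor converted to chill at a
    delivery event; equals 0.5 at the transition temperature Tf and
    increases strictly with temperature."""
    tf_k = params.Tf + KELVIN_OFFSET
    s = math.exp(params.slope * tf_k * (temp_k - tf_k) / temp_k)
    return s / (1.0 + s)


def chill_step(state: ChillState, temp_k: float,
               params: ChillSubmodelParams) -> ChillState:
    """Advance the Dynamic Model by one hour at temperature ``temp_k``."""
    if not math.isfinite(temp_k) or temp_k <= 0:
        raise ValueError(f"temperature must be finite and positive (K), got {temp_k}")
    k1 = params.A1 * math.exp(-params.E1 / temp_k)
    xs = (params.A0 / params.A1) * math.exp((params.E1 - params.E0) / temp_k)
    xp = xs - (xs - state.x) * math.exp(-k1)
    if xp >= 1.0:
        xi = conversion_fraction(temp_k, params)
        return ChillState(x=xp * (1.0 - xi), y=state.y + xi * xp)
    return ChillState(x=xp, y=state.y)


def accumulate_chill(hourly_c: Sequence[float] | np.ndarray,
                     params: ChillSubmodelParams) -> np.ndarray:
    """Chill-portion trajectory (y after each hour) for an hourly °C
    series, starting from x = 0, y = 0.  Empty input yields an empty
    trajectory."""
    temp_c = np.asarray(hourly_c, dtype=np.float64)
    if temp_c.size == 0:
        return np.empty(0, dtype=np.float64)
    if not np.all(np.isfinite(temp_c)):
        raise ValueError("temperature series contains non-finite values")
    return _kernels.chill_trajectory(
        temp_c + KELVIN_OFFSET,
        params.E0, params.E1, params.A0, params.A1,
        params.Tf + KELVIN_OFFSET, params.slope,
    )


def hours_to_first_portion(temp_k_constant: float,
                           params: ChillSubmodelParams,
                           max_hours: int = 2000) -> int:
    """Hour (1-based) of the first chill-portion delivery under constant
    exposure, or -1 if none occurs within ``max_hours``."""
    temps = np.full(max_hours, float(temp_k_constant))
    return int(_kernels.first_conversion_hour(
        temps, params.E0, params.E1, params.A0, params.A1))


# ---------------------------------------------------------------------------
# Intermediate -> canonical reparameterization


@dataclass(frozen=True)
class NegationCycle:
    """Square-wave temperature cycle used to give ``pie_c`` quantitative
    meaning: a fraction ``cool_fraction`` of each cycle period is spent at
    theta_star and the rest at ``warm_k``.  ``pie_c`` is the cycle period at
    which the cycle just fails to deliver chill portions (the asymptotic
    per-cycle precursor maximum equals 1).  The warm temperature and duty
    fraction follow the controlled-experiment tradition of alternating a
    near-optimal chilling temperature with a warm (~19 °C) phase; both are
    configurable because the literature fixes the concept, not the cycle."""

    warm_k: float = 292.0
    cool_fraction: float = 0.25


_DELTA_LO = 50.0
_DELTA_HI = 2.0e5


def _solve_pieces(delta: float, theta_star: float, theta_c: float,
                  tau: float):
    """Given the energy gap delta = E1 - E0, return (u, L, E1, k1_star)
    implied by the optimality of theta_star and the tau timing condition;
    u = ln xs(theta_star), L = -ln(1 - 1/xs(theta_star))."""
    u = delta * (1.0 / theta_star - 1.0 / theta_c)
    v = math.exp(-u)
    L = -math.log1p(-v)
    E1 = delta * v / ((1.0 - v) * L)
    k1_star = L / tau
    return u, L, E1, k1_star


def _cycle_excess(delta: float, ip: IntermediateChillParams,
                  cycle: NegationCycle) -> float:
    """Asymptotic per-cycle precursor maximum minus 1 for the negation
    cycle run at period pie_c (linearized square-wave fixed point)."""
    ts, tc = ip.theta_star, ip.theta_c
    u, L, E1, k1_star = _solve_pieces(delta, ts, tc, ip.tau)
    # k1(warm) = k1(theta_star) * exp(E1*(1/theta_star - 1/warm)); formed
    # in log space so large trial energy gaps do not overflow.
    log_k1_warm = math.log(k1_star) + E1 * (1.0 / ts - 1.0 / cycle.warm_k)
    k1_warm = math.exp(min(log_k1_warm, 700.0))
    xs_star = math.exp(u)
    xs_warm = math.exp(delta * (1.0 / cycle.warm_k - 1.0 / tc))
    cool = cycle.cool_fraction * ip.pie_c
    warm = (1.0 - cycle.cool_fraction) * ip.pie_c
    a_c = math.exp(-k1_star * cool)
    a_w = math.exp(-k1_warm * warm)
    x_max = (xs_star * (1.0 - a_c) + xs_warm * a_c * (1.0 - a_w)) / (
        1.0 - a_c * a_w)
    return x_max - 1.0


def intermediate_to_canonical(
    ip: IntermediateChillParams,
    cycle: NegationCycle = NegationCycle(),
) -> tuple[float, float, float, float]:
    """Map intermediate chill parameters to canonical (E0, E1, A0, A1).

    The mapping enforces, exactly:

    (a) steady state at the critical temperature — xs(theta_c) = 1, so
        constant exposure at or above theta_c delivers no portions (A0 is
        nudged by at most a few ulps so this also holds in floating point);
    (b) timing at the optimum — starting from x = 0 at constant
        theta_star, the precursor first reaches 1 after exactly tau hours
        (continuous time), hence the first simulated portion arrives at
        hour ceil(tau);
    (c) optimality of theta_star — the time-to-first-portion as a function
        of constant temperature is stationary (minimal) at theta_star;
    (d) negation period — the configured cool/warm cycle run at period
        pie_c sits exactly at the chill-negation threshold.

    Conditions (a)-(c) determine three of the four degrees of freedom in
    closed form given the energy gap E1 - E0; condition (d) pins the gap by
    bracketed root-finding, making the mapping deterministic and continuous
    in ``ip``.
    """
    ts = ip.theta_star
    tc = ip.theta_c
    f_lo = _cycle_excess(_DELTA_LO, ip, cycle)
    f_hi = _cycle_excess(_DELTA_HI, ip, cycle)
    if f_lo * f_hi > 0:
        raise ValueError(
            "no canonical parameter set satisfies the chill-negation "
            f"condition for {ip} with cycle {cycle}")
    delta = brentq(_cycle_excess, _DELTA_LO, _DELTA_HI, args=(ip, cycle),
                   xtol=1e-9, rtol=1e-14)
    _, L, E1, k1_star = _solve_pieces(delta, ts, tc, ip.tau)
    A1 = k1_star * math.exp(E1 / ts)
    E0 = E1 - delta
    A0 = A1 * math.exp(-delta / tc)
    # Bias xs(theta_c) to <= 1 in float arithmetic: a value a few ulps above
    # 1 would let the precursor cross 1 spuriously under long exposure at
    # theta_c, breaking the defining no-accumulation property.
    while (A0 / A1) * math.exp((E1 - E0) / tc) > 1.0:
        A0 = math.nextafter(A0, 0.0)
    return E0, E1, A0, A1


def canonical_chill_params(
    ip: IntermediateChillParams,
    Tf: float,
    slope: float,
    cycle: NegationCycle = NegationCycle(),
) -> ChillSubmodelParams:
    """Convenience wrapper bundling the converted kinetics with the
    conversion-sigmoid parameters."""
    E0, E1, A0, A1 = intermediate_to_canonical(ip, cycle)
    return ChillSubmodelParams(E0=E0, E1=E1, A0=A0, A1=A1, Tf=Tf, slope=slope)
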