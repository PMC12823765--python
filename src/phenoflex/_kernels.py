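"""Numba-compiled inner loops.

The hourly recursions are inherently sequential, so they are JIT-compiled
rather than vectorized.  All kernels take plain floats/arrays; parameter
objects are unpacked by the calling modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit

KELVIN_OFFSET = 273.0


@njit(cache=False)
def chill_trajectory(temp_k, E0, E1, A0, A1, tf_k, slope):
    """Accumulated chill portions y after each hourly step (same length as
    input).  Implements the two-step Dynamic Model recursion: the precursor
    x relaxes toward its temperature-dependent steady state, and whenever it
    reaches 1 a sigmoidal fraction converts irreversibly into chill."""
    n = temp_k.shape[0]
    y_out = np.empty(n, dtype=np.float64)
    x = 0.0
    y = 0.0
    for i in range(n):
        tk = temp_k[i]
        k1 = A1 * np.exp(-E1 / tk)
        xs = (A0 / A1) * np.exp((E1 - E0) / tk)
        xp = xs - (xs - x) * np.exp(-k1)
        if xp >= 1.0:
            s = np.exp(slope * tf_k * (tk - tf_k) / tk)
            xi = s / (1.0 + s)
            y += xi * xp
            x = xp * (1.0 - xi)
        else:
            x = xp
        y_out[i] = y
    return y_out


@njit(cache=False)
def first_conversion_hour(temp_k, E0, E1, A0, A1):
    """1-based hour of the first chill-portion delivery (first time the
    precursor reaches 1), or -1 if it never does.  The conversion fraction
    does not affect the timing of the first event."""
    x = 0.0
    for i in range(temp_k.shape[0]):
        tk = temp_k[i]
        k1 = A1 * np.exp(-E1 / tk)
        xs = (A0 / A1) * np.exp((E1 - E0) / tk)
        xp = xs - (xs - x) * np.exp(-k1)
        if xp >= 1.0:
            return i + 1
        x = xp
    return -1


@njit(cache=False, inline="always")
def _gdh(tc, Tb, Tu, Tc):
    if tc <= Tb or tc >= Tc:
        return 0.0
    if tc <= Tu:
        return 0.5 * (Tu - Tb) * (
            1.0 + np.cos(np.pi + np.pi * (tc - Tb) / (Tu - Tb))
        )
    return (Tu - Tb) * (
        1.0 + np.cos(0.5 * np.pi + 0.5 * np.pi * (tc - Tu) / (Tc - Tu))
    )


@njit(cache=False)
def gdh_values(temp_c, Tb, Tu, Tc):
    n = temp_c.shape[0]
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        out[i] = _gdh(temp_c[i], Tb, Tu, Tc)
    return out


@njit(cache=False)
def bloom_hour(temp_c, E0, E1, A0, A1, tf_k, slope, Tb, Tu, Tc, yc, zc, s1):
    """0-based hour at which gated heat accumulation first reaches zc, or
    -1 for failure to bloom.  Heat is accumulated in normalized GDH units
    (hourly response divided by its maximum Tu - Tb) weighted by the
    logistic chill gate 1/(1+exp(-s1*(y-yc)))."""
    x = 0.0
    y = 0.0
    z = 0.0
    scale = 1.0 / (Tu - Tb)
    for i in range(temp_c.shape[0]):
        tk = temp_c[i] + KELVIN_OFFSET
        k1 = A1 * np.exp(-E1 / tk)
        xs = (A0 / A1) * np.exp((E1 - E0) / tk)
        xp = xs - (xs - x) * np.exp(-k1)
        if xp >= 1.0:
            s = np.exp(slope * tf_k * (tk - tf_k) / tk)
            xi = s / (1.0 + s)
            y += xi * xp
            x = xp * (1.0 - xi)
        else:
            x = xp
        w = 1.0 / (1.0 + np.exp(-s1 * (y - yc)))
        z += w * _gdh(temp_c[i], Tb, Tu, Tc) * scale
        if z >= zc:
            return i
    return -1


@njit(cache=False)
def chill_heat_traces(temp_c, E0, E1, A0, A1, tf_k, slope, Tb, Tu, Tc,
                      yc, zc, s1):
    """Full hourly chill (y) and gated normalized heat (z) trajectories."""
    n = temp_c.shape[0]
    y_out = np.empty(n, dtype=np.float64)
    z_out = np.empty(n, dtype=np.float64)
    x = 0.0
    y = 0.0
    z = 0.0
    scale = 1.0 / (Tu - Tb)
    for i in range(n):
        tk = temp_c[i] + KELVIN_OFFSET
        k1 = A1 * np.exp(-E1 / tk)
        xs = (A0 / A1) * np.exp((E1 - E0) / tk)
        xp = xs - (xs - x) * np.exp(-k1)
        if xp >= 1.0:
            s = np.exp(slope * tf_k * (tk - tf_k) / tk)
            xi = s / (1.0 + s)
            y += xi * xp
            x = xp * (1.0 - xi)
        else:
            x = xp
        w = 1.0 / (1.0 + np.exp(-s1 * (y - yc)))
        z += w * _gdh(temp_c[i], Tb, Tu, Tc) * scale
        y_out[i] = y
        z_out[i] = z
    return y_out, z_out


@njit(cache=False)
def bloom_time_continuous(temp_c, E0, E1, A0, A1, tf_k, slope,
                          Tb, Tu, Tc, yc, zc, s1):
    """Continuous bloom time in hours from season start (linear
    interpolation of the zc crossing within the hour), or -1 with the
    final gated-heat total if the requirement is never met.  Returns
    (hours, z_final)."""
    x = 0.0
    y = 0.0
    z = 0.0
    scale = 1.0 / (Tu - Tb)
    for i in range(temp_c.shape[0]):
        tk = temp_c[i] + KELVIN_OFFSET
        k1 = A1 * np.exp(-E1 / tk)
        xs = (A0 / A1) * np.exp((E1 - E0) / tk)
        xp = xs - (xs - x) * np.exp(-k1)
        if xp >= 1.0:
            s = np.exp(slope * tf_k * (tk - tf_k) / tk)
            xi = s / (1.0 + s)
            y += xi * xp
            x = xp * (1.0 - xi)
        else:
            x = xp
        w = 1.0 / (1.0 + np.exp(-s1 * (y - yc)))
        dz = w * _gdh(temp_c[i], Tb, Tu, Tc) * scale
        z_new = z + dz
        if z_new >= zc:
            frac = (zc - z) / dz if dz > 0.0 else 0.0
            return i + frac, z_new
        z = z_new
    return -1.0, z


@njit(cache=False)
def bloom_residuals_tabled(temp_idx_2d, lengths, start_doys, end_doys,
                           obs_doys, xs_tab, ek_tab, xi_tab, g_tab,
                           yc, zc, s1, no_bloom_extra):
    """Same residuals as :func:`bloom_residuals`, but with all
    temperature-dependent terms looked up from precomputed tables over the
    quantized temperature grid (xs, exp(-k1), conversion fraction, scaled
    GDH).  The logistic heat gate is recomputed only when accumulated
    chill changes, which it does at most once per hour."""
    m = temp_idx_2d.shape[0]
    res = np.empty(m, dtype=np.float64)
    for j in range(m):
        x = 0.0
        y = 0.0
        z = 0.0
        w = 1.0 / (1.0 + np.exp(s1 * yc))  # gate at y = 0
        L = lengths[j]
        bloomed = False
        for i in range(L):
            t = temp_idx_2d[j, i]
            xs = xs_tab[t]
            xp = xs - (xs - x) * ek_tab[t]
            if xp >= 1.0:
                xi = xi_tab[t]
                y += xi * xp
                x = xp * (1.0 - xi)
                w = 1.0 / (1.0 + np.exp(-s1 * (y - yc)))
            else:
                x = xp
            dz = w * g_tab[t]
            z_new = z + dz
            if z_new >= zc:
                frac = (zc - z) / dz if dz > 0.0 else 0.0
                res[j] = start_doys[j] + (i + frac) / 24.0 \
                    - (obs_doys[j] + 0.5)
                bloomed = True
                break
            z = z_new
        if not bloomed:
            res[j] = end_doys[j] - obs_doys[j] + no_bloom_extra \
                + 100.0 * (zc - z) / zc
    return res


@njit(cache=False)
def gated_heat_at_hours(temp_idx_2d, lengths, target_hours,
                        xs_tab, ek_tab, xi_tab, g_tab, yc, s1):
    """Accumulated gated (normalized) heat at a target hour of each season
    row, using the same tabled recursion as the residual kernel.  Used to
    profile the heat requirement: the zc that would make each season bloom
    exactly at its observed hour."""
    m = temp_idx_2d.shape[0]
    out = np.empty(m, dtype=np.float64)
    for j in range(m):
        x = 0.0
        y = 0.0
        z = 0.0
        w = 1.0 / (1.0 + np.exp(s1 * yc))
        stop = min(target_hours[j], lengths[j])
        for i in range(stop):
            t = temp_idx_2d[j, i]
            xs = xs_tab[t]
            xp = xs - (xs - x) * ek_tab[t]
            if xp >= 1.0:
                xi = xi_tab[t]
                y += xi * xp
                x = xp * (1.0 - xi)
                w = 1.0 / (1.0 + np.exp(-s1 * (y - yc)))
            else:
                x = xp
            z += w * g_tab[t]
        out[j] = z
    return out


@njit(cache=False)
def bloom_residuals(temps_2d, start_doys, end_doys, obs_doys,
                    E0, E1, A0, A1, tf_k, slope, Tb, Tu, Tc, yc, zc, s1,
                    no_bloom_extra):
    """Smooth residuals (predicted - observed bloom day) for a stack of
    seasons sharing one parameter set.  Predictions are continuous
    (fractional days); an observed calendar day d stands for the interval
    [d, d+1) and enters as its midpoint d + 0.5, so the continuous residual
    is unbiased with respect to day-granularity observations.  Failure to
    bloom yields the penalty residual (season-end DOY - observed DOY +
    no_bloom_extra) plus a heat-shortfall term so the penalty shrinks
    continuously as the model approaches blooming."""
    m = temps_2d.shape[0]
    res = np.empty(m, dtype=np.float64)
    for j in range(m):
        h, z_final = bloom_time_continuous(
            temps_2d[j], E0, E1, A0, A1, tf_k, slope,
            Tb, Tu, Tc, yc, zc, s1)
        if h < 0.0:
            shortfall = (zc - z_final) / zc
            res[j] = end_doys[j] - obs_doys[j] + no_bloom_extra \
                + 100.0 * shortfall
        else:
            res[j] = start_doys[j] + h / 24.0 - (obs_doys[j] + 0.5)
    return res
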