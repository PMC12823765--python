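"""Independent straight-line reference implementations used as oracles.

Deliberately minimal and written directly from the model definitions with
plain Python floats and ``math`` only — no imports from the package's
numerical internals — so agreement is a genuine cross-check.
"""

import math

KELVIN = 273.0


def ref_chill_trajectory(temps_c, E0, E1, A0, A1, Tf_c, slope):
    """Hour-by-hour Dynamic Model loop; returns list of accumulated chill."""
    x = 0.0
    y = 0.0
    tf_k = Tf_c + KELVIN
    out = []
    for t_c in temps_c:
        tk = t_c + KELVIN
        k1 = A1 * math.exp(-E1 / tk)
        xs = (A0 / A1) * math.exp((E1 - E0) / tk)
        x_new = xs - (xs - x) * math.exp(-k1)
        if x_new >= 1.0:
            s = math.exp(slope * tf_k * (tk - tf_k) / tk)
            xi = s / (1.0 + s)
            y = y + xi * x_new
            x = x_new * (1.0 - xi)
        else:
            x = x_new
        out.append(y)
    return out


def ref_gdh(t_c, Tb, Tu, Tc):
    if t_c <= Tb or t_c >= Tc:
        return 0.0
    if t_c <= Tu:
        return (Tu - Tb) / 2.0 * (
            1.0 + math.cos(math.pi + math.pi * (t_c - Tb) / (Tu - Tb)))
    return (Tu - Tb) * (
        1.0 + math.cos(math.pi / 2.0 + math.pi / 2.0 * (t_c - Tu) / (Tc - Tu)))


def ref_gdh_accumulation(temps_c, Tb, Tu, Tc, weights=None):
    total = 0.0
    out = []
    for i, t_c in enumerate(temps_c):
        w = 1.0 if weights is None else weights[i]
        total += w * ref_gdh(t_c, Tb, Tu, Tc)
        out.append(total)
    return out


def ref_bloom_hour(temps_c, E0, E1, A0, A1, Tf_c, slope, Tb, Tu, Tc,
                   yc, zc, s1):
    """0-based hour at which gated normalized heat reaches zc, else -1."""
    x = 0.0
    y = 0.0
    z = 0.0
    tf_k = Tf_c + KELVIN
    for i, t_c in enumerate(temps_c):
        tk = t_c + KELVIN
        k1 = A1 * math.exp(-E1 / tk)
        xs = (A0 / A1) * math.exp((E1 - E0) / tk)
        x_new = xs - (xs - x) * math.exp(-k1)
        if x_new >= 1.0:
            s = math.exp(slope * tf_k * (tk - tf_k) / tk)
            xi = s / (1.0 + s)
            y = y + xi * x_new
            x = x_new * (1.0 - xi)
        else:
            x = x_new
        w = 1.0 / (1.0 + math.exp(-s1 * (y - yc)))
        z += w * ref_gdh(t_c, Tb, Tu, Tc) / (Tu - Tb)
        if z >= zc:
            return i
    return -1
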