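"""Growing Degree Hours (GDH) forcing accumulation.

The hourly heat response is the classic piecewise-cosine curve: zero at or
below the base temperature Tb, rising to its maximum (Tu - Tb) at the
optimum Tu, falling back to zero at the critical temperature Tc, and zero
beyond.  The stress factor of the original formulation is fixed at 1.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import _kernels
from .params import HeatSubmodelParams


def gdh_hour(temp_c: float, params: HeatSubmodelParams) -> float:
    """Heat units contributed by one hour at ``temp_c`` (°C)."""
    return float(_kernels._gdh(float(temp_c), params.Tb, params.Tu, params.Tc))


def accumulate_gdh(
    hourly_c: Sequence[float] | np.ndarray,
    params: HeatSubmodelParams,
    weights: Sequence[float] | np.ndarray | None = None,
) -> np.ndarray:
    """Cumulative (optionally weighted) GDH trajectory.

    ``weights`` are per-hour multipliers in [0, 1] (e.g. the chill gate of
    the coupled bloom model); all ones when omitted.
    """
    temp_c = np.asarray(hourly_c, dtype=np.float64)
    vals = _kernels.gdh_values(temp_c, params.Tb, params.Tu, params.Tc)
    if weights is not None:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != temp_c.shape:
            raise ValueError(
                f"weights length {w.shape} does not match series {temp_c.shape}")
        vals = vals * w
    return np.cumsum(vals)
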