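"""Desirability transforms and the total-performance scalarization.

Each response is normalized onto [0, 1] by a linear ramp between a lower
and an upper specification limit: the crowding index EDWIN^C enters as a
larger-the-better ramp (d1) and the per-patient system time ST as a
smaller-the-better ramp (d2).  The scalar objective combined from the two
is TP = d1 * d2^2, which doubles the weight on the time response and is
the fitness maximized by the genetic algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ExplicitBoundsError, InvalidBoundsError, InvalidParameterError

__all__ = [
    "DesirabilityBounds",
    "d_ramp_up",
    "d_ramp_down",
    "bounds_from_responses",
    "total_performance",
    "desirability_pair",
]


@dataclass(frozen=True)
class DesirabilityBounds:
    """Specification limits for the two responses."""

    edwinc_min: float
    edwinc_max: float
    st_min: float
    st_max: float

    def __post_init__(self) -> None:
        if not self.edwinc_min < self.edwinc_max:
            raise InvalidBoundsError("edwinc_min must be < edwinc_max")
        if not self.st_min < self.st_max:
            raise InvalidBoundsError("st_min must be < st_max")


def d_ramp_up(value: float, lo: float, hi: float) -> float:
    """Larger-the-better linear ramp: 0 below ``lo``, 1 above ``hi``."""
    if not lo < hi:
        raise InvalidBoundsError(f"need lo < hi, got {lo} >= {hi}")
    if value <= lo:
        return 0.0
    if value >= hi:
        return 1.0
    return (value - lo) / (hi - lo)


def d_ramp_down(value: float, lo: float, hi: float) -> float:
    """Smaller-the-better linear ramp: 1 below ``lo``, 0 above ``hi``."""
    if not lo < hi:
        raise InvalidBoundsError(f"need lo < hi, got {lo} >= {hi}")
    if value <= lo:
        return 1.0
    if value >= hi:
        return 0.0
    return (value - hi) / (lo - hi)


def bounds_from_responses(
    means: pd.DataFrame, margin: float = 0.0
) -> DesirabilityBounds:
    """Specification limits from observed cell-mean extrema.

    ``margin`` widens each range symmetrically by that fraction of its
    width.  Constant responses have no usable range; set the bounds
    explicitly in that case.
    """
    if margin < 0:
        raise InvalidParameterError("margin must be >= 0")
    out: dict[str, float] = {}
    for col, prefix in (("mean_edwinc", "edwinc"), ("mean_st", "st")):
        if col not in means.columns:
            raise InvalidParameterError(f"responses lack column {col!r}")
        values = means[col].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        if values.size < 2 or np.min(values) == np.max(values):
            raise ExplicitBoundsError(
                f"{col} is degenerate; provide explicit desirability bounds"
            )
        lo, hi = float(np.min(values)), float(np.max(values))
        pad = margin * (hi - lo)
        out[f"{prefix}_min"], out[f"{prefix}_max"] = lo - pad, hi + pad
    return DesirabilityBounds(**out)


def desirability_pair(
    mean_edwinc: float,
    mean_st: float,
    bounds: DesirabilityBounds,
    edwinc_orientation: str = "ltb",
) -> tuple[float, float]:
    """(d1, d2) for one response pair.

    The default orientation treats EDWIN^C as larger-the-better; pass
    ``edwinc_orientation='stb'`` for the clinically intuitive direction.
    """
    if edwinc_orientation == "ltb":
        d1 = d_ramp_up(mean_edwinc, bounds.edwinc_min, bounds.edwinc_max)
    elif edwinc_orientation == "stb":
        d1 = d_ramp_down(mean_edwinc, bounds.edwinc_min, bounds.edwinc_max)
    else:
        raise InvalidParameterError("edwinc_orientation must be 'ltb' or 'stb'")
    d2 = d_ramp_down(mean_st, bounds.st_min, bounds.st_max)
    return d1, d2


def total_performance(d1: float, d2: float) -> float:
    """TP = d1 * d2^2 — the scalar total performance and GA fitness."""
    for name, v in (("d1", d1), ("d2", d2)):
        if not 0.0 <= v <= 1.0:
            raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")
    return d1 * d2 * d2
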