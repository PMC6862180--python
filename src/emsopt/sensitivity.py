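"""One-factor-at-a-time sensitivity around the optimized factor setting.

Each control factor is swept over its grid while the other three stay at
the optimum; every cell reports the total performance TP and the adjusted
TP%, the relative drop from the optimum's TP:

    adjusted TP% = (TP_level - TP_opt) / TP_opt * 100,

rounded half-away-from-zero to two decimals.  Factor A uses the grid
1.0, 1.2, ..., 3.0; factors B-D use their three levels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Sequence

import pandas as pd

from .config import SensitivitySettings
from .errors import InvalidParameterError
from .ga import Chromosome

__all__ = ["SensitivityTable", "adjusted_tp_percent", "ofat_sweep"]


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SensitivityTable:
    factor: str
    levels: tuple[float, ...]
    tp: tuple[float, ...]
    adjusted_tp_percent: tuple[float, ...]
    tp_opt: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                f"factor_{self.factor}": self.levels,
                "tp": self.tp,
                "adjusted_tp_percent": self.adjusted_tp_percent,
            }
        )


def adjusted_tp_percent(tp_level: float, tp_opt: float) -> float:
    """Relative TP change from the optimum, in percent to two decimals."""
    if tp_opt <= 0:
        raise InvalidParameterError("tp_opt must be > 0")
    return _round2((tp_level - tp_opt) / tp_opt * 100.0)


def ofat_sweep(
    fitness: Callable[[Chromosome], float],
    optimum: Chromosome,
    tp_opt: float | None = None,
    settings: SensitivitySettings | None = None,
) -> Mapping[str, SensitivityTable]:
    """Sweep each factor around ``optimum``; others held at their optimal value.

    ``fitness`` is the same TP evaluation the optimizer used (surrogate
    prediction aggregated over the signal/noise combinations), so the
    tables are internally consistent with the reported optimum.  If
    ``tp_opt`` is omitted it is recomputed at ``optimum``.
    """
    settings = settings or SensitivitySettings()
    if tp_opt is None:
        tp_opt = fitness(optimum)
    if tp_opt <= 0:
        raise InvalidParameterError("optimum TP must be > 0 for adjusted percentages")

    grids: dict[str, Sequence[float]] = {
        "A": settings.factor_a_grid,
        "B": (1, 2, 3),
        "C": (1, 2, 3),
        "D": (1, 2, 3),
    }
    out: dict[str, SensitivityTable] = {}
    for factor, grid in grids.items():
        tps = []
        for level in grid:
            if factor == "A":
                chrom = dataclasses.replace(optimum, factor_A=float(level))
            else:
                chrom = dataclasses.replace(optimum, **{f"factor_{factor}": int(level)})
            tps.append(fitness(chrom))
        out[factor] = SensitivityTable(
            factor=factor,
            levels=tuple(float(l) for l in grid),
            tp=tuple(tps),
            adjusted_tp_percent=tuple(adjusted_tp_percent(t, tp_opt) for t in tps),
            tp_opt=tp_opt,
        )
    return out
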