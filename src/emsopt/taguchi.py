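"""Dynamic Taguchi robust-design layer.

The experiment crosses an L9(3^4) inner array over the four control
factors with the two signal levels (1 or 2 physicians) and the two noise
levels (350 or 425 patients/day), giving 9 x 2 x 2 = 36 cells; each cell
is simulated for a configured number of replications.  For each inner row
and response, a zero-intercept ideal function ``y_ij = beta * M_j`` is
fitted through the cell means and the dynamic signal-to-noise ratio

    SN = 10 * log10(beta / MSE)   [decibels]

is computed (an option provides the conventional ``beta^2 / MSE`` form).
Main effects average SN per factor level; the optimal setting takes the
level with maximal mean SN per factor, with the usual additive prediction
of SN at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig, TaguchiSettings
from .errors import InfiniteSNError, InsufficientDataError, InvalidParameterError
from .simulate import run_simulation

__all__ = [
    "l9_array",
    "DesignCell",
    "DesignPlan",
    "build_plan",
    "run_plan",
    "cell_means",
    "fit_ideal_function",
    "sn_ratio",
    "sn_table",
    "main_effects",
    "select_optimal_levels",
    "FACTORS",
]

FACTORS = ("A", "B", "C", "D")

# Standard L9(3^4) orthogonal array.
_L9 = np.array(
    [
        [1, 1, 1, 1],
        [1, 2, 2, 2],
        [1, 3, 3, 3],
        [2, 1, 2, 3],
        [2, 2, 3, 1],
        [2, 3, 1, 2],
        [3, 1, 3, 2],
        [3, 2, 1, 3],
        [3, 3, 2, 1],
    ],
    dtype=int,
)


def l9_array() -> np.ndarray:
    """The standard L9(3^4) array: 9 runs x 4 three-level columns."""
    return _L9.copy()


@dataclass(frozen=True)
class DesignCell:
    row: int  # 0-based L9 row index
    levels: tuple[int, int, int, int]  # (A, B, C, D)
    signal_M: int
    noise_lambda: float

    def scenario(self, base: ScenarioConfig) -> ScenarioConfig:
        a, b, c, d = self.levels
        return base.replace(
            signal_M=self.signal_M,
            noise_lambda=self.noise_lambda,
            factor_A=float(a),
            factor_B=b,
            factor_C=c,
            factor_D=d,
        )


@dataclass(frozen=True)
class DesignPlan:
    inner_rows: np.ndarray
    signal_levels: tuple[int, ...]
    noise_levels: tuple[float, ...]
    cells: tuple[DesignCell, ...]
    replications: int
    base_config: ScenarioConfig = field(default_factory=ScenarioConfig)


def build_plan(
    signal_levels: tuple[int, ...] = (1, 2),
    noise_levels: tuple[float, ...] = (350.0, 425.0),
    replications: int = 1000,
    base_config: ScenarioConfig | None = None,
) -> DesignPlan:
    """Cross the L9 inner array with the signal and noise levels.

    The default crossing yields the 36-cell plan (9 rows x 2 x 2).
    """
    if len(set(signal_levels)) != len(signal_levels):
        raise InvalidParameterError("duplicate signal levels")
    if len(set(noise_levels)) != len(noise_levels):
        raise InvalidParameterError("duplicate noise levels")
    if replications < 1:
        raise InvalidParameterError("replications must be >= 1")
    base = base_config if base_config is not None else ScenarioConfig()
    rows = l9_array()
    cells = tuple(
        DesignCell(row=i, levels=tuple(int(v) for v in rows[i]), signal_M=int(m), noise_lambda=float(z))
        for i in range(rows.shape[0])
        for m in signal_levels
        for z in noise_levels
    )
    return DesignPlan(
        inner_rows=rows,
        signal_levels=tuple(signal_levels),
        noise_levels=tuple(noise_levels),
        cells=cells,
        replications=replications,
        base_config=base,
    )


def _replication_seed(master_seed: int, cell_index: int, rep: int) -> int:
    # documented counter scheme: one SeedSequence child per (cell, rep)
    ss = np.random.SeedSequence([int(master_seed), int(cell_index), int(rep)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_plan(plan: DesignPlan, master_seed: int = 0) -> pd.DataFrame:
    """Simulate every cell x replication; one tidy row per replication.

    Columns: row, A..D, M, Z, rep, mean_st, mean_edwinc.  Replication
    seeds derive from ``master_seed`` by a per-(cell, replication) counter
    scheme, so individual cells can be re-run independently.
    """
    records = []
    for ci, cell in enumerate(plan.cells):
        for rep in range(plan.replications):
            cfg = cell.scenario(plan.base_config).replace(
                seed=_replication_seed(master_seed, ci, rep)
            )
            result = run_simulation(cfg)
            a, b, c, d = cell.levels
            records.append(
                {
                    "row": cell.row,
                    "A": a,
                    "B": b,
                    "C": c,
                    "D": d,
                    "M": cell.signal_M,
                    "Z": cell.noise_lambda,
                    "rep": rep,
                    "mean_st": result.mean_ST,
                    "mean_edwinc": result.mean_EDWINC,
                }
            )
    return pd.DataFrame.from_records(records)


def cell_means(responses: pd.DataFrame) -> pd.DataFrame:
    """Mean response per design cell (over replications)."""
    keys = ["row", "A", "B", "C", "D", "M", "Z"]
    return (
        responses.groupby(keys, as_index=False)[["mean_st", "mean_edwinc"]]
        .mean()
        .sort_values(keys, ignore_index=True)
    )


def fit_ideal_function(
    M_values: np.ndarray, y_values: np.ndarray, ddof: int = 1
) -> tuple[float, float]:
    """Zero-intercept least squares of ``y = beta * M``.

    Returns ``(beta, mse)`` with ``beta = sum(M*y)/sum(M^2)`` and
    ``mse = sum((y - beta*M)^2) / (n - ddof)``.
    """
    m = np.asarray(M_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if m.shape != y.shape:
        raise InvalidParameterError("M_values and y_values must have equal length")
    n = m.size
    if n < 2:
        raise InsufficientDataError("need at least two (M, y) pairs")
    denom = float(np.sum(m * m))
    if denom == 0.0:
        raise InvalidParameterError("all signal values are zero")
    beta = float(np.sum(m * y) / denom)
    resid = y - beta * m
    mse = float(np.sum(resid**2) / (n - ddof))
    return beta, mse


def sn_ratio(
    beta: float, mse: float, variant: str = "beta", negative_slope: str = "abs"
) -> float:
    """Dynamic signal-to-noise ratio in decibels.

    ``variant='beta'`` computes ``10*log10(beta/MSE)``;
    ``'conventional'`` computes ``10*log10(beta^2/MSE)``.  A negative
    slope is handled per ``negative_slope``: ``'abs'`` (default) uses
    ``|beta|``; ``'raise'`` treats it as a domain error.
    """
    if variant not in ("beta", "conventional"):
        raise InvalidParameterError(f"unknown SN variant {variant!r}")
    if mse <= 0:
        raise InfiniteSNError("MSE must be > 0 for a finite SN ratio")
    if beta == 0:
        raise InvalidParameterError("beta = 0 has no defined SN ratio")
    if beta < 0 and negative_slope == "raise":
        raise InvalidParameterError("beta <= 0 is outside the SN form's domain")
    b = abs(beta)
    num = b if variant == "beta" else b * b
    return float(10.0 * math.log10(num / mse))


def sn_table(
    means: pd.DataFrame,
    response: str,
    settings: TaguchiSettings | None = None,
) -> pd.DataFrame:
    """Per-L9-row ideal-function fit and SN ratio for one response column.

    With ``pool_noise`` (default), the responses entering the fit are the
    cell means at each (signal, noise) combination, so noise-to-noise
    variation contributes to the MSE — the robustness reading of the
    dynamic design.  Otherwise one fit per noise level is averaged.
    """
    settings = settings or TaguchiSettings()
    if response not in means.columns:
        raise InvalidParameterError(f"response {response!r} not in cell means")
    rows = []
    for row, grp in means.groupby("row"):
        if settings.pool_noise:
            beta, mse = fit_ideal_function(
                grp["M"].to_numpy(), grp[response].to_numpy(), ddof=settings.mse_ddof
            )
            sn = sn_ratio(beta, mse, settings.sn_variant)
        else:
            fits = [
                fit_ideal_function(g["M"].to_numpy(), g[response].to_numpy(), settings.mse_ddof)
                for _, g in grp.groupby("Z")
            ]
            beta = float(np.mean([b for b, _ in fits]))
            mse = float(np.mean([m for _, m in fits]))
            sn = sn_ratio(beta, mse, settings.sn_variant)
        levels = grp.iloc[0]
        rows.append(
            {
                "row": int(row),
                "A": int(levels["A"]),
                "B": int(levels["B"]),
                "C": int(levels["C"]),
                "D": int(levels["D"]),
                "beta": beta,
                "beta_sign": int(np.sign(beta)),
                "mse": mse,
                "sn_db": sn,
            }
        )
    out = pd.DataFrame(rows).sort_values("row", ignore_index=True)
    if len(out) != 9:
        raise InsufficientDataError(f"expected 9 inner rows, got {len(out)}")
    return out


def main_effects(sn_df: pd.DataFrame) -> pd.DataFrame:
    """Mean SN per factor level (three rows per (factor, level) by L9 balance)."""
    if len(sn_df) != 9 or not set(FACTORS) <= set(sn_df.columns):
        raise InsufficientDataError("main_effects requires a complete 9-row SN table")
    records = []
    for factor in FACTORS:
        for level in (1, 2, 3):
            sel = sn_df[sn_df[factor] == level]
            if len(sel) != 3:
                raise InsufficientDataError(f"L9 balance violated for {factor} level {level}")
            records.append(
                {"factor": factor, "level": level, "mean_sn": float(sel["sn_db"].mean())}
            )
    return pd.DataFrame(records)


def select_optimal_levels(effects: pd.DataFrame) -> tuple[dict[str, int], float]:
    """Level with maximal mean SN per factor, plus the additive SN prediction.

    Ties go to the lower level index.  The prediction is
    ``overall mean + sum(chosen level mean - overall mean)``.
    """
    if set(effects["factor"]) != set(FACTORS):
        raise InsufficientDataError("effects table must cover factors A-D")
    # overall mean of the 9 SN values = mean of any factor's level means
    overall = float(effects.groupby("factor")["mean_sn"].mean().mean())
    setting: dict[str, int] = {}
    predicted = overall
    for factor in FACTORS:
        sub = effects[effects["factor"] == factor].sort_values("level")
        best = sub.loc[sub["mean_sn"].idxmax()]
        setting[factor] = int(best["level"])
        predicted += float(best["mean_sn"]) - overall
    return setting, predicted
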