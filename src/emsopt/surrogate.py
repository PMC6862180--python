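"""Feed-forward neural-network surrogate of the simulated response surface.

A single-hidden-layer perceptron with sigmoid activations maps the six
scaled inputs (signal level, noise level, control factors A-D) to the two
desirabilities (d1, d2).  Training is full-batch backpropagation with
momentum 0.65 and a bold-driver learning rate clamped to [0.01, 0.5] for
10,000 iterations by default; the architecture search trains one model
per hidden-node count (2..8 by default) and keeps the structure with the
smallest test RMSE, mirroring a 6-h-2 structure comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SurrogateSettings
from .desirability import DesirabilityBounds, desirability_pair
from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "TrainingTable",
    "SurrogateModel",
    "build_training_table",
    "train",
    "architecture_search",
    "predict",
]

INPUT_COLUMNS = ("M", "Z", "A", "B", "C", "D")


@dataclass(frozen=True)
class TrainingTable:
    """Scaled design-cell inputs with desirability targets and a fixed split."""

    X: np.ndarray  # (n, 6), scaled to [0, 1]
    Y: np.ndarray  # (n, 2), (d1, d2)
    train_mask: np.ndarray  # boolean, True = training row
    input_min: np.ndarray  # (6,) affine scaler parameters (raw units)
    input_max: np.ndarray
    frame: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_train(self) -> int:
        return int(self.train_mask.sum())

    @property
    def n_test(self) -> int:
        return int((~self.train_mask).sum())


def _train_count(n: int, fraction: float) -> int:
    # round-half-up on the train count (0.8 * 36 = 28.8 -> 29)
    return int(np.floor(fraction * n + 0.5))


def build_training_table(
    means: pd.DataFrame,
    bounds: DesirabilityBounds,
    settings: SurrogateSettings | None = None,
    seed: int = 0,
) -> TrainingTable:
    """One row per design cell; targets from the desirability transforms.

    The train/test split is a seeded shuffle with a round-half-up train
    count, so the 36-cell plan splits 29 / 7 at the default 0.8 fraction.
    """
    settings = settings or SurrogateSettings()
    missing = [c for c in (*INPUT_COLUMNS, "mean_st", "mean_edwinc") if c not in means.columns]
    if missing:
        raise InvalidParameterError(f"cell means lack columns {missing}")
    frame = means.reset_index(drop=True).copy()
    if frame[["mean_st", "mean_edwinc"]].isna().any().any():
        raise InsufficientDataError("cell means contain missing responses")
    X_raw = frame[list(INPUT_COLUMNS)].to_numpy(dtype=float)
    targets = np.array(
        [
            desirability_pair(ew, st, bounds, settings.edwinc_orientation)
            for ew, st in zip(frame["mean_edwinc"], frame["mean_st"])
        ]
    )
    lo = X_raw.min(axis=0)
    hi = X_raw.max(axis=0)
    if np.any(hi <= lo):
        flat = [INPUT_COLUMNS[i] for i in np.where(hi <= lo)[0]]
        raise InvalidParameterError(f"input column(s) {flat} are constant; cannot scale")
    X = (X_raw - lo) / (hi - lo)

    n = len(frame)
    order = np.random.default_rng(seed).permutation(n)
    mask = np.zeros(n, dtype=bool)
    mask[order[: _train_count(n, settings.train_fraction)]] = True
    frame["split"] = np.where(mask, "train", "test")
    frame["d1"] = targets[:, 0]
    frame["d2"] = targets[:, 1]
    return TrainingTable(X=X, Y=targets, train_mask=mask, input_min=lo, input_max=hi, frame=frame)


@dataclass
class SurrogateModel:
    """Trained 6-h-2 sigmoid network with its scalers and fit diagnostics."""

    hidden_nodes: int
    W1: np.ndarray  # (6, h)
    b1: np.ndarray  # (h,)
    W2: np.ndarray  # (h, 2)
    b2: np.ndarray  # (2,)
    input_min: np.ndarray
    input_max: np.ndarray
    rmse_train: float
    rmse_test: float
    iterations: int
    momentum: float
    lr_bounds: tuple[float, float]
    seed: int

    @property
    def structure(self) -> tuple[int, int, int]:
        return (6, self.hidden_nodes, 2)

    def forward_scaled(self, X: np.ndarray) -> np.ndarray:
        H = _sigmoid(X @ self.W1 + self.b1)
        return _sigmoid(H @ self.W2 + self.b2)

    def to_json(self) -> str:
        payload = {
            "structure": list(self.structure),
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "input_min": self.input_min.tolist(),
            "input_max": self.input_max.tolist(),
            "rmse_train": self.rmse_train,
            "rmse_test": self.rmse_test,
            "iterations": self.iterations,
            "momentum": self.momentum,
            "lr_bounds": list(self.lr_bounds),
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SurrogateModel":
        d = json.loads(text)
        return cls(
            hidden_nodes=int(d["structure"][1]),
            W1=np.asarray(d["W1"]),
            b1=np.asarray(d["b1"]),
            W2=np.asarray(d["W2"]),
            b2=np.asarray(d["b2"]),
            input_min=np.asarray(d["input_min"]),
            input_max=np.asarray(d["input_max"]),
            rmse_train=float(d["rmse_train"]),
            rmse_test=float(d["rmse_test"]),
            iterations=int(d["iterations"]),
            momentum=float(d["momentum"]),
            lr_bounds=tuple(d["lr_bounds"]),
            seed=int(d["seed"]),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def _rmse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - target) ** 2)))


def train(
    table: TrainingTable,
    hidden_nodes: int,
    settings: SurrogateSettings | None = None,
    seed: int = 0,
) -> SurrogateModel:
    """Backpropagation with momentum and a clamped bold-driver learning rate.

    The learning rate grows 5% after an iteration that lowered the loss
    and halves after one that raised it, always clamped to the configured
    [lr_min, lr_max] window.  Deterministic given ``seed``.
    """
    settings = settings or SurrogateSettings()
    if hidden_nodes < 1:
        raise InvalidParameterError("hidden_nodes must be >= 1")
    Xtr, Ytr = table.X[table.train_mask], table.Y[table.train_mask]
    if Xtr.size == 0:
        raise InsufficientDataError("empty training table")
    rng = np.random.default_rng(seed)
    h = hidden_nodes
    W1 = rng.normal(0.0, 0.5, size=(6, h))
    b1 = np.zeros(h)
    W2 = rng.normal(0.0, 0.5, size=(h, 2))
    b2 = np.zeros(2)
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)

    lr = settings.lr_min
    mom = settings.momentum
    prev_loss = np.inf
    for _ in range(settings.iterations):
        H = _sigmoid(Xtr @ W1 + b1)
        P = _sigmoid(H @ W2 + b2)
        err = P - Ytr
        loss = float(np.mean(err**2))
        # bold driver: reward a decrease, punish an increase
        lr = min(lr * 1.05, settings.lr_max) if loss < prev_loss else max(lr * 0.5, settings.lr_min)
        prev_loss = loss

        d2 = err * P * (1.0 - P) * (2.0 / err.size)
        gW2 = H.T @ d2
        gb2 = d2.sum(axis=0)
        d1 = (d2 @ W2.T) * H * (1.0 - H)
        gW1 = Xtr.T @ d1
        gb1 = d1.sum(axis=0)

        vW1 = mom * vW1 - lr * gW1
        vb1 = mom * vb1 - lr * gb1
        vW2 = mom * vW2 - lr * gW2
        vb2 = mom * vb2 - lr * gb2
        W1 += vW1
        b1 += vb1
        W2 += vW2
        b2 += vb2

    model = SurrogateModel(
        hidden_nodes=h,
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        input_min=table.input_min.copy(),
        input_max=table.input_max.copy(),
        rmse_train=0.0,
        rmse_test=0.0,
        iterations=settings.iterations,
        momentum=mom,
        lr_bounds=(settings.lr_min, settings.lr_max),
        seed=seed,
    )
    model.rmse_train = _rmse(model.forward_scaled(Xtr), Ytr)
    Xte, Yte = table.X[~table.train_mask], table.Y[~table.train_mask]
    model.rmse_test = _rmse(model.forward_scaled(Xte), Yte) if Xte.size else float("nan")
    return model


def architecture_search(
    table: TrainingTable,
    settings: SurrogateSettings | None = None,
    seed: int = 0,
) -> tuple[SurrogateModel, pd.DataFrame]:
    """Train one model per hidden-node count; keep the minimal test RMSE.

    Returns the winning model and a comparison table with one row per
    candidate structure (``6-h-2``, training RMSE, testing RMSE).
    """
    settings = settings or SurrogateSettings()
    models = []
    rows = []
    for i, h in enumerate(settings.hidden_range):
        child = int(np.random.SeedSequence([seed, h]).generate_state(1, dtype=np.uint32)[0] % 2**31)
        model = train(table, h, settings, seed=child)
        models.append(model)
        rows.append(
            {
                "structure": f"6-{h}-2",
                "hidden_nodes": h,
                "rmse_train": model.rmse_train,
                "rmse_test": model.rmse_test,
            }
        )
    comparison = pd.DataFrame(rows)
    pick_col = "rmse_test" if comparison["rmse_test"].notna().all() else "rmse_train"
    best = models[int(comparison[pick_col].idxmin())]
    return best, comparison


def predict(
    model: SurrogateModel,
    signal: float,
    noise: float,
    factor_A: float,
    factor_B: float,
    factor_C: float,
    factor_D: float,
) -> tuple[float, float]:
    """Forward pass at one factor setting; returns (d1, d2) in [0, 1].

    Inputs outside the recorded scaler ranges are clamped with a warning
    (factor A may be fractional anywhere inside its range).
    """
    raw = np.array([signal, noise, factor_A, factor_B, factor_C, factor_D], dtype=float)
    if np.any(raw < model.input_min - 1e-9) or np.any(raw > model.input_max + 1e-9):
        warnings.warn("surrogate queried outside its training range; inputs clamped",
                      RuntimeWarning, stacklevel=2)
        raw = np.clip(raw, model.input_min, model.input_max)
    x = (raw - model.input_min) / (model.input_max - model.input_min)
    out = model.forward_scaled(x[None, :])[0]
    return float(np.clip(out[0], 0.0, 1.0)), float(np.clip(out[1], 0.0, 1.0))
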