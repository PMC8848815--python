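"""Weighted training-set cost for model-parameter fitting.

The cost is the standard weighted sum of squared residuals

    E(p) = sum_i [ w_i (y_i - f(x_i, p)) / sigma_i ]^2

with per-item reference values ``y_i``, importance weights ``w_i`` and unit
scales ``sigma_i`` that make contributions of different physical units
comparable. The model callable is supplied by the user; the per-item
residuals are exposed as extras so termination criteria can watch, e.g.,
a validation subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ..core_log import Bounds
from .base import Task

__all__ = ["TrainingSetCost", "training_cost", "read_training_set"]


@dataclass
class TrainingSetCost:
    """A training set plus the model it constrains.

    ``model(x_i, p)`` returns the prediction for item ``i`` under parameters
    ``p``; ``inputs`` holds the per-item conditions ``x_i`` (any sequence).
    """

    y: np.ndarray
    w: np.ndarray
    sigma: np.ndarray
    model: Callable
    inputs: Sequence = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.y.size
        if self.w.size != n or self.sigma.size != n:
            raise ValueError("y, w and sigma must have equal length")
        if np.any(self.sigma == 0.0):
            raise ValueError("sigma entries must be nonzero")
        if not self.inputs:
            self.inputs = list(range(n))
        elif len(self.inputs) != n:
            raise ValueError("inputs must match training-set length")

    @property
    def n_items(self) -> int:
        return self.y.size

    def predictions(self, p: np.ndarray) -> np.ndarray:
        return np.array([self.model(xi, p) for xi in self.inputs], dtype=float)


def training_cost(
    p: np.ndarray, ts: TrainingSetCost, return_residuals: bool = False
):
    """Weighted sum-of-squares cost; optionally also the weighted residuals."""
    yhat = ts.predictions(np.asarray(p, dtype=float))
    resid = ts.w * (ts.y - yhat) / ts.sigma
    cost = float(np.sum(resid * resid))
    if return_residuals:
        return cost, resid
    return cost


def training_task(
    ts: TrainingSetCost, bounds: Bounds, name: str = "training_cost"
) -> Task:
    return Task(
        name=name,
        bounds=bounds,
        evaluate=lambda p: training_cost(p, ts),
        extras_fn=lambda p: {"residuals": training_cost(p, ts, True)[1]},
    )


def read_training_set(path, model: Callable, inputs: Sequence = ()) -> TrainingSetCost:
    """Load a training set from CSV with header columns ``y``, ``w``, ``sigma``."""
    df = pd.read_csv(path)
    missing = {"y", "w", "sigma"} - set(df.columns)
    if missing:
        raise ValueError(f"training-set CSV missing columns: {sorted(missing)}")
    return TrainingSetCost(
        y=df["y"].to_numpy(),
        w=df["w"].to_numpy(),
        sigma=df["sigma"].to_numpy(),
        model=model,
        inputs=list(inputs),
    )
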