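"""Bounded objective functions with optional gradients and known-minimum metadata."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ..core_log import Bounds

__all__ = ["Task"]


@dataclass
class Task:
    """A bounded minimization target.

    ``evaluate`` maps a parameter vector to a scalar (lower is better) and may
    additionally return a dict of named extras via :meth:`evaluate_with_extras`.
    ``evaluate_batch``, when set, evaluates a whole (n, d) matrix at once and
    is used by population-based children to cut per-call overhead.
    """

    name: str
    bounds: Bounds
    evaluate: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray] | None = None
    evaluate_batch: Callable[[np.ndarray], np.ndarray] | None = None
    extras_fn: Callable[[np.ndarray], dict] | None = None
    known_min_f: float | None = None
    known_min_x: np.ndarray | None = None

    @property
    def dimension(self) -> int:
        return self.bounds.dimension

    def __call__(self, x: np.ndarray) -> float:
        return float(self.evaluate(np.asarray(x, dtype=float)))

    def evaluate_with_extras(self, x: np.ndarray) -> tuple[float, dict]:
        x = np.asarray(x, dtype=float)
        f = float(self.evaluate(x))
        extras = self.extras_fn(x) if self.extras_fn is not None else {}
        return f, extras

    def batch(self, X: np.ndarray) -> np.ndarray:
        """Evaluate n points; falls back to a Python loop without a batch op."""
        X = np.asarray(X, dtype=float)
        if self.evaluate_batch is not None:
            return np.asarray(self.evaluate_batch(X), dtype=float)
        return np.array([self.evaluate(x) for x in X], dtype=float)
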