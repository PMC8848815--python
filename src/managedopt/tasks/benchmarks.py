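"""Classic global-optimization benchmark functions.

All four functions are multimodal in qualitatively different ways:

* Schwefel: no global trend toward the minimum, which hides near the boundary
  of a large box; the runner-up basin is far from the winner.
* Rastrigin: globally unimodal envelope with a dense oscillatory overlay.
* Deceptive (type III): a tiny basin of attraction around a customizable
  global minimizer, with the immediate neighbourhood sloping away from it.
* Shubert (4-D product form): periodically repeated, exactly degenerate
  global minima surrounded by very good runner-up solutions.

A small 4-D "trap" fixture is included as the canonical example of a function
on which solution-injection strategies must fail: corners with more zero
coordinates have lower values, yet the global minimum is the all-ones corner.
"""

from __future__ import annotations

import numpy as np

from ..core_log import Bounds
from .base import Task

__all__ = [
    "schwefel",
    "rastrigin",
    "deceptive",
    "shubert4",
    "trap",
    "schwefel_task",
    "rastrigin_task",
    "deceptive_task",
    "shubert4_task",
    "trap_task",
    "SCHWEFEL_XSTAR",
    "TRAP_CORNERS",
]

#: Per-coordinate global minimizer of the Schwefel function on [-500, 500],
#: to the precision conventionally printed.
SCHWEFEL_XSTAR = 420.9687


def schwefel(x: np.ndarray) -> float:
    """Schwefel value ``418.9829 d - sum(x_i sin(sqrt(|x_i|)))``."""
    x = np.asarray(x, dtype=float)
    return float(418.9829 * x.size - np.sum(x * np.sin(np.sqrt(np.abs(x)))))


def _schwefel_batch(X: np.ndarray) -> np.ndarray:
    return 418.9829 * X.shape[1] - np.sum(X * np.sin(np.sqrt(np.abs(X))), axis=1)


def schwefel_task(dimension: int = 20) -> Task:
    b = Bounds([-500.0] * dimension, [500.0] * dimension)
    return Task(
        name=f"schwefel{dimension}",
        bounds=b,
        evaluate=schwefel,
        evaluate_batch=_schwefel_batch,
        known_min_x=np.full(dimension, SCHWEFEL_XSTAR),
        known_min_f=0.0,
    )


def rastrigin(x: np.ndarray) -> float:
    """Rastrigin value ``10 d + sum(x_i^2 - 10 cos(2 pi x_i))``; 0 at the origin."""
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def _rastrigin_batch(X: np.ndarray) -> np.ndarray:
    return 10.0 * X.shape[1] + np.sum(X * X - 10.0 * np.cos(2.0 * np.pi * X), axis=1)


def rastrigin_task(dimension: int = 66) -> Task:
    b = Bounds([-5.12] * dimension, [5.12] * dimension)
    return Task(
        name=f"rastrigin{dimension}",
        bounds=b,
        evaluate=rastrigin,
        evaluate_batch=_rastrigin_batch,
        known_min_x=np.zeros(dimension),
        known_min_f=0.0,
    )


def _deceptive_g(x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-dimension tent profile peaking (value 1) exactly at alpha.

    Piecewise linear on [0, 1] with a narrow peak of half-width (1-alpha)/5 or
    alpha/5 around alpha and gentle slopes toward 4/5 at the box edges, so the
    region just outside the peak slopes *away* from the global minimizer.
    """
    g = np.empty_like(x)
    lo = x <= 0.8 * alpha
    g[lo] = 0.8 - x[lo] / alpha[lo]
    mid_l = (x > 0.8 * alpha) & (x <= alpha)
    g[mid_l] = 5.0 * x[mid_l] / alpha[mid_l] - 4.0
    mid_r = (x > alpha) & (x <= (1.0 + 4.0 * alpha) / 5.0)
    g[mid_r] = 5.0 * (x[mid_r] - alpha[mid_r]) / (alpha[mid_r] - 1.0) + 1.0
    hi = x > (1.0 + 4.0 * alpha) / 5.0
    g[hi] = (x[hi] - 1.0) / (1.0 - alpha[hi]) + 0.8
    return g


def deceptive(x: np.ndarray, min_location: np.ndarray, beta: float = 2.0) -> float:
    """Type-III deceptive function on the unit box; minimum -1 at ``min_location``."""
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(min_location, dtype=float)
    if np.any(alpha <= 0.0) or np.any(alpha >= 1.0):
        raise ValueError("min_location must lie strictly inside the unit box")
    return float(-((np.mean(_deceptive_g(x, alpha))) ** beta))


def deceptive_task(
    dimension: int = 20,
    min_location: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> Task:
    """Deceptive task; the minimizer is randomized per instance unless given."""
    if min_location is None:
        rng = rng if rng is not None else np.random.default_rng()
        # keep the peak away from the very edge so its basin is inside the box
        min_location = rng.uniform(0.1, 0.9, size=dimension)
    alpha = np.asarray(min_location, dtype=float)
    b = Bounds(np.zeros(dimension), np.ones(dimension))

    def _batch(X: np.ndarray) -> np.ndarray:
        return np.array([deceptive(x, alpha) for x in X])

    return Task(
        name=f"deceptive{dimension}",
        bounds=b,
        evaluate=lambda x: deceptive(x, alpha),
        evaluate_batch=_batch,
        known_min_x=alpha.copy(),
        known_min_f=-1.0,
    )


def _shubert_term(x: np.ndarray) -> np.ndarray:
    j = np.arange(1.0, 6.0)
    return np.sum(j * np.cos((j + 1.0) * x[..., None] + j), axis=-1)


def shubert4(x: np.ndarray) -> float:
    """4-D Shubert function: product over dimensions of the 5-cosine sum.

    Global minima are exactly degenerate and repeat with period 2*pi along
    every axis; the global value is near -3.93e4 on the [-10, 10]^4 box.
    """
    x = np.asarray(x, dtype=float)
    if x.size != 4:
        raise ValueError("shubert4 is defined for 4-dimensional input")
    return float(np.prod(_shubert_term(x)))


def _shubert4_batch(X: np.ndarray) -> np.ndarray:
    return np.prod(_shubert_term(X), axis=1)


def shubert4_task() -> Task:
    b = Bounds([-10.0] * 4, [10.0] * 4)
    return Task(
        name="shubert4",
        bounds=b,
        evaluate=shubert4,
        evaluate_batch=_shubert4_batch,
    )


#: The five corner anchors of the trap fixture: more zeros -> lower value,
#: but the true minimum sits at the all-ones corner.
TRAP_CORNERS: tuple[tuple[tuple[float, float, float, float], float], ...] = (
    ((1.0, 1.0, 1.0, 1.0), 0.0),
    ((0.0, 1.0, 1.0, 1.0), 4.0),
    ((0.0, 0.0, 1.0, 1.0), 3.0),
    ((0.0, 0.0, 0.0, 1.0), 2.0),
    ((0.0, 0.0, 0.0, 0.0), 1.0),
)


def trap(x: np.ndarray) -> float:
    """Nearest listed corner's anchor value plus a quadratic bowl around it."""
    x = np.asarray(x, dtype=float)
    if x.size != 4:
        raise ValueError("trap is defined for 4-dimensional input")
    corners = np.array([c for c, _ in TRAP_CORNERS])
    values = np.array([v for _, v in TRAP_CORNERS])
    d2 = np.sum((corners - x) ** 2, axis=1)
    k = int(np.argmin(d2))  # ties -> first listed corner
    return float(values[k] + d2[k])


def trap_task() -> Task:
    b = Bounds(np.zeros(4), np.ones(4))
    return Task(
        name="trap",
        bounds=b,
        evaluate=trap,
        evaluate_batch=lambda X: np.array([trap(x) for x in X]),
        known_min_x=np.ones(4),
        known_min_f=0.0,
    )
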