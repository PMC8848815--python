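"""Covariance matrix adaptation evolution strategy (CMA-ES), ask/tell style.

A self-contained (mu/mu_w, lambda)-CMA-ES with the standard dimension-
dependent defaults: population size lambda = 4 + floor(3 ln d) (17 at d=87),
log-linear recombination weights, cumulation paths for step size and rank-one
covariance updates, and rank-mu update. The initial step size defaults to
half the bound box width so the starting location is deliberately
uninformative and the early search is global.

The ask/tell split exists so callers can manipulate the sampled population
before evaluation — the solution-injection ("nudging") child relies on this:
``tell`` re-derives each candidate's displacement from the current mean, so
candidates need not be the exact points ``ask`` produced.

Convergence ("natural" stopping) follows the customary function-value
criterion: the spread of the per-iteration best values over the last
``10 + ceil(30 d / lambda)`` iterations falls below ``tolfun``.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .core_log import Bounds

__all__ = ["CMAES", "default_population_size", "sigma0_default"]


def default_population_size(dimension: int) -> int:
    """The dimension-dependent default lambda = 4 + floor(3 ln d)."""
    if dimension < 1:
        raise ValueError("dimension must be positive")
    return 4 + int(3 * math.log(dimension))


def sigma0_default(bounds: Bounds) -> float:
    """Initial global step size: half the box width.

    For non-uniform boxes the mean per-dimension half-width is used.
    """
    return float(np.mean(bounds.widths) / 2.0)


class CMAES:
    """One CMA-ES instance with clip-to-box bound handling.

    Parameters
    ----------
    x0 : start mean.
    sigma0 : initial step size; defaults to half the box width when bounds
        are given.
    bounds : optional box; sampled candidates are clipped into it before they
        are returned by :meth:`ask` (and hence before evaluation).
    popsize : population size; defaults to ``default_population_size``.
    tolfun : function-value convergence tolerance.
    max_evals : hard safety cap on evaluations; the run reports convergence
        (reason ``"max_evals"``) when it is reached.
    """

    def __init__(
        self,
        x0: Sequence[float],
        sigma0: float | None = None,
        bounds: Bounds | None = None,
        popsize: int | None = None,
        seed: int | None = None,
        tolfun: float = 1e-11,
        max_evals: float | None = None,
    ):
        self.mean = np.asarray(x0, dtype=float).copy()
        n = self.mean.size
        self.n = n
        if sigma0 is None:
            if bounds is None:
                raise ValueError("sigma0 required when no bounds are given")
            sigma0 = sigma0_default(bounds)
        if sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        self.sigma = float(sigma0)
        self.sigma0 = float(sigma0)
        self.bounds = bounds
        self.tolfun = float(tolfun)
        self.max_evals = math.inf if max_evals is None else float(max_evals)
        self.rng = np.random.default_rng(seed)

        lam = default_population_size(n) if popsize is None else int(popsize)
        if lam < 2:
            raise ValueError("population size must be at least 2")
        self.lam = lam
        mu = lam // 2
        w = np.log((lam + 1) / 2.0) - np.log(np.arange(1, mu + 1))
        self.weights = w / np.sum(w)
        self.mu = mu
        self.mueff = float(1.0 / np.sum(self.weights**2))

        # strategy parameter defaults (Hansen's tutorial values)
        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(
            1 - self.c1,
            2 * (self.mueff - 2 + 1 / self.mueff) / ((n + 2) ** 2 + self.mueff),
        )
        self.damps = (
            1 + 2 * max(0.0, math.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.cs
        )
        self.chiN = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self._B = np.eye(n)
        self._D = np.ones(n)
        self._eigen_stale = 0
        self._eigen_interval = max(1, int(1.0 / ((self.c1 + self.cmu) * n * 10.0)))

        self.iteration = 0
        self.evals = 0
        self._window = 10 + math.ceil(30 * n / lam)
        self._best_history: list[float] = []
        self.best_x = self.mean.copy()
        self.best_f = math.inf
        self.stop_reason: str | None = None

    # -- sampling -----------------------------------------------------------

    def ask(self) -> np.ndarray:
        """Sample lambda candidates (clipped into bounds), shape (lambda, n)."""
        if self._eigen_stale >= self._eigen_interval:
            self._update_eigen()
        Z = self.rng.standard_normal((self.lam, self.n))
        X = self.mean + self.sigma * (Z * self._D) @ self._B.T
        if self.bounds is not None:
            X = self.bounds.clip(X)
        return X

    def _update_eigen(self) -> None:
        self.C = (self.C + self.C.T) / 2.0
        d2, B = np.linalg.eigh(self.C)
        self._D = np.sqrt(np.maximum(d2, 1e-40))
        self._B = B
        self._eigen_stale = 0

    # -- update -------------------------------------------------------------

    def tell(self, X: np.ndarray, f: Sequence[float]) -> None:
        """Rank candidates and apply the standard CMA update.

        Non-finite objective values are treated as +inf (worst rank).
        """
        X = np.asarray(X, dtype=float)
        f = np.asarray(f, dtype=float)
        f = np.where(np.isfinite(f), f, np.inf)
        if X.shape != (self.lam, self.n) or f.size != self.lam:
            raise ValueError("tell expects the full population of this instance")

        self.iteration += 1
        self.evals += self.lam
        order = np.argsort(f, kind="stable")
        if f[order[0]] < self.best_f:
            self.best_f = float(f[order[0]])
            self.best_x = X[order[0]].copy()

        old_mean = self.mean
        sel = X[order[: self.mu]]
        new_mean = self.weights @ sel
        y_mean = (new_mean - old_mean) / self.sigma

        # step-size path uses C^(-1/2) y
        c_inv_half_y = self._B @ ((self._B.T @ y_mean) / self._D)
        self.ps = (1 - self.cs) * self.ps + math.sqrt(
            self.cs * (2 - self.cs) * self.mueff
        ) * c_inv_half_y
        ps_norm = float(np.linalg.norm(self.ps))
        hsig = ps_norm / math.sqrt(
            1 - (1 - self.cs) ** (2 * (self.iteration))
        ) / self.chiN < 1.4 + 2 / (self.n + 1)

        self.pc = (1 - self.cc) * self.pc + (
            math.sqrt(self.cc * (2 - self.cc) * self.mueff) * y_mean
            if hsig
            else 0.0
        )

        Y = (sel - old_mean) / self.sigma
        rank_mu = (self.weights[:, None] * Y).T @ Y
        delta_hsig = (1 - hsig) * self.cc * (2 - self.cc)
        self.C = (
            (1 - self.c1 - self.cmu) * self.C
            + self.c1 * (np.outer(self.pc, self.pc) + delta_hsig * self.C)
            + self.cmu * rank_mu
        )
        self._eigen_stale += 1

        # exponent clamped at 1: guards against degenerate populations
        # (e.g. repeated identical injected candidates) blowing up the path
        self.sigma *= math.exp(
            min(1.0, (self.cs / self.damps) * (ps_norm / self.chiN - 1))
        )
        self.sigma = float(np.clip(self.sigma, 1e-300, 1e300))
        self.mean = new_mean

        self._best_history.append(float(f[order[0]]))
        if len(self._best_history) > self._window:
            del self._best_history[0]
        if (
            len(self._best_history) == self._window
            and max(self._best_history) - min(self._best_history) < self.tolfun
        ):
            self.stop_reason = "tolfun"
        elif self.evals >= self.max_evals:
            self.stop_reason = self.stop_reason or "max_evals"

    # -- status -------------------------------------------------------------

    @property
    def converged(self) -> bool:
        return self.stop_reason is not None

    @property
    def result(self) -> tuple[np.ndarray, float, int]:
        return self.best_x, self.best_f, self.evals
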