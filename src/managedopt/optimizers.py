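"""Child optimizers: the contracts the manager supervises.

A child exposes a tiny protocol: ``step()`` performs one optimizer iteration
(for CMA-ES, one ask/evaluate/tell cycle of lambda evaluations) and returns
the evaluations to be pushed to the central log; ``converged`` reports the
child's natural stopping criterion; ``stop()`` is the manager's forced
termination; ``tell_best`` receives the manager's incumbent broadcast.

Two CMA-based kinds exist:

* ``cma`` — plain CMA-ES.
* ``ncma`` — nudging CMA-ES: the child holds an injected candidate (the best
  point it has ever been told of, initially its start point) and, every
  ``injection_period`` iterations, forces that candidate into the sampled
  population in place of one sample. The injections repeatedly pull the
  distribution mean back toward the good solution without the exploration
  collapse of true elitism. With ``injection_period = inf`` the child is
  bit-identical to plain CMA-ES under the same seed.

``local_bfgs`` children wrap a scipy BFGS local search (analytic gradients
when the task provides them) and are the lower half of basin-hopping-style
managed strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable

import numpy as np
from scipy import optimize as sciopt

from .cmaes import CMAES, default_population_size, sigma0_default
from .core_log import Bounds
from .tasks import Task

__all__ = [
    "ChildConfig",
    "CMAChild",
    "LocalSearchChild",
    "make_child",
    "local_search",
    "default_population_size",
    "sigma0_default",
]


@dataclass(frozen=True)
class ChildConfig:
    """Declarative description of one child optimizer.

    ``push_interval`` thins only what is transmitted to the manager's log
    ("send every nth evaluation"); the child's internal state always sees
    every evaluation.
    """

    kind: str = "cma"  # cma | ncma | local_bfgs
    tolfun: float = 1e-11
    max_iterations: int | None = None
    seed: int | None = None
    push_interval: int = 1
    popsize: int | None = None
    sigma0: float | None = None
    injection_period: float = 10
    max_evals: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cma", "ncma", "local_bfgs"):
            raise ValueError(f"unknown child kind {self.kind!r}")
        if self.tolfun <= 0:
            raise ValueError("tolfun must be positive")
        if self.push_interval < 1:
            raise ValueError("push_interval must be >= 1")
        if self.injection_period is not None and self.injection_period < 1:
            raise ValueError("injection_period must be >= 1")


class _ChildBase:
    """Shared bookkeeping: eval counting, push thinning, end state."""

    def __init__(self, child_id: Hashable, task: Task, config: ChildConfig):
        self.child_id = child_id
        self.task = task
        self.config = config
        self.evals_used = 0
        self._push_counter = 0
        self.stopped = False
        self.best_x: np.ndarray | None = None
        self.best_f = math.inf

    def _account(self, x: np.ndarray, f: float, extras=None):
        """Count one evaluation; return the record if it should be pushed."""
        self.evals_used += 1
        if f < self.best_f:
            self.best_f = f
            self.best_x = np.asarray(x, dtype=float).copy()
        self._push_counter += 1
        if self._push_counter >= self.config.push_interval:
            self._push_counter = 0
            return (x, f, extras)
        return None

    def stop(self) -> None:
        self.stopped = True

    def tell_best(self, x: np.ndarray, f: float) -> None:  # noqa: ARG002
        """Manager incumbent broadcast; plain children ignore it."""

    @property
    def converged(self) -> bool:
        raise NotImplementedError

    def step(self) -> list[tuple]:
        raise NotImplementedError


class CMAChild(_ChildBase):
    """CMA-ES child, optionally with periodic solution injection (nudging)."""

    def __init__(
        self,
        child_id: Hashable,
        task: Task,
        config: ChildConfig,
        start: np.ndarray,
        initial_candidate: tuple[np.ndarray, float] | None = None,
    ):
        super().__init__(child_id, task, config)
        self.nudging = config.kind == "ncma"
        self.es = CMAES(
            x0=start,
            sigma0=config.sigma0,
            bounds=task.bounds,
            popsize=config.popsize,
            seed=config.seed,
            tolfun=config.tolfun,
            max_evals=config.max_evals,
        )
        self.injection_period = (
            math.inf if config.injection_period is None else config.injection_period
        )
        # initial nudging candidate: what the manager seeded, else the start
        if initial_candidate is not None:
            x0, f0 = initial_candidate
            self.injected_x = task.bounds.clip(np.asarray(x0, dtype=float))
            self.injected_f = float(f0)
        else:
            self.injected_x = np.asarray(start, dtype=float).copy()
            self.injected_f = math.inf

    def tell_best(self, x: np.ndarray, f: float) -> None:
        if self.nudging and f < self.injected_f:
            self.injected_x = self.task.bounds.clip(np.asarray(x, dtype=float))
            self.injected_f = float(f)

    def step(self) -> list[tuple]:
        if self.converged or self.stopped:
            return []
        X = self.es.ask()
        if (
            self.nudging
            and np.isfinite(self.injection_period)
            and (self.es.iteration + 1) % int(self.injection_period) == 0
        ):
            # forced injection: replace one (exchangeable) sample, unless the
            # candidate is already present, keeping lambda unchanged
            if not np.any(np.all(X == self.injected_x, axis=1)):
                X = X.copy()
                X[-1] = self.injected_x
        f = self.task.batch(X)
        self.es.tell(X, f)
        pushed = []
        for xi, fi in zip(X, f):
            rec = self._account(xi, float(fi))
            if rec is not None:
                pushed.append(rec)
        if self.nudging and self.best_f < self.injected_f:
            self.injected_x = self.best_x.copy()
            self.injected_f = self.best_f
        if (
            self.config.max_iterations is not None
            and self.es.iteration >= self.config.max_iterations
        ):
            self.es.stop_reason = self.es.stop_reason or "max_iterations"
        return pushed

    @property
    def converged(self) -> bool:
        return self.es.converged


class LocalSearchChild(_ChildBase):
    """A single BFGS local search run as a managed child.

    The whole search executes on the first ``step()`` call (the scipy driver
    is not incrementally resumable); every objective evaluation is still
    pushed to the log, so budget accounting is exact.
    """

    def __init__(
        self,
        child_id: Hashable,
        task: Task,
        config: ChildConfig,
        start: np.ndarray,
    ):
        super().__init__(child_id, task, config)
        self.start = np.asarray(start, dtype=float)
        self._done = False
        self.result_x: np.ndarray | None = None
        self.result_f: float | None = None

    def step(self) -> list[tuple]:
        if self._done or self.stopped:
            return []
        self._done = True
        pushed: list[tuple] = []

        def fun(x):
            fx = self.task(x)
            rec = self._account(x, fx)
            if rec is not None:
                pushed.append(rec)
            if (
                self.config.max_evals is not None
                and self.evals_used >= self.config.max_evals
            ):
                raise _EvalBudgetExhausted
            return fx

        try:
            res = sciopt.minimize(
                fun,
                self.start,
                method="BFGS",
                jac=self.task.gradient,
                options={"gtol": 1e-5},
            )
            self.result_x, self.result_f = res.x, float(res.fun)
        except _EvalBudgetExhausted:
            self.result_x, self.result_f = self.best_x, self.best_f
        return pushed

    @property
    def converged(self) -> bool:
        return self._done


class _EvalBudgetExhausted(Exception):
    pass


def local_search(
    start: np.ndarray,
    task: Task,
    max_evals: float | None = None,
    gtol: float = 1e-5,
):
    """BFGS local minimization from ``start``; returns (x*, f*, evals used).

    Uses the task's analytic gradient when available, finite differences
    otherwise. Stops at ``max_evals`` (returning the best point seen so far)
    or at gradient norm <= ``gtol``. Raises for a non-finite objective at the
    start point.
    """
    start = np.asarray(start, dtype=float)
    f0 = task(start)
    if not np.isfinite(f0):
        raise ValueError("objective is not finite at the start point")

    state = {"n": 0, "best_x": start, "best_f": f0}

    def fun(x):
        state["n"] += 1
        fx = task(x)
        if fx < state["best_f"]:
            state["best_f"] = fx
            state["best_x"] = np.asarray(x, dtype=float).copy()
        if max_evals is not None and state["n"] >= max_evals:
            raise _EvalBudgetExhausted
        return fx

    try:
        res = sciopt.minimize(
            fun, start, method="BFGS", jac=task.gradient, options={"gtol": gtol}
        )
        x, fx = res.x, float(res.fun)
    except _EvalBudgetExhausted:
        x, fx = state["best_x"], state["best_f"]
    return x, fx, state["n"]


def make_child(
    child_id: Hashable,
    task: Task,
    config: ChildConfig,
    start: np.ndarray,
    initial_candidate: tuple[np.ndarray, float] | None = None,
) -> _ChildBase:
    """Instantiate the child class matching ``config.kind``."""
    if config.kind in ("cma", "ncma"):
        return CMAChild(child_id, task, config, start, initial_candidate)
    return LocalSearchChild(child_id, task, config, start)
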