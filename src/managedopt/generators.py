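"""Start-point generators and child-configuration selectors.

Generators produce the starting location for each newly spawned child. The
simple ones (random, incumbent) are stateless given the log; the
Monte-Carlo ones own a single accepted-reference chain, in the style of
basin-hopping (fixed temperature) and generalized simulated annealing
(cooling temperature with restarts), and fold finished-child results into
that chain in order of arrival — the serializable adaptation of an
inherently sequential upper-level algorithm to an asynchronous manager.

Selectors pick which child configuration to spawn next from a pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_log import Bounds, CentralLog
from .optimizers import ChildConfig

__all__ = [
    "Generator",
    "RandomGenerator",
    "IncumbentGenerator",
    "BasinHoppingGenerator",
    "AnnealingGenerator",
    "make_generator",
    "Selector",
    "SingleSelector",
    "RoundRobinSelector",
    "StagedSelector",
]


class Generator:
    """Produces start points; ``tell`` folds a finished child's result in."""

    def ask(self, log: CentralLog, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def tell(self, x: np.ndarray, f: float, rng: np.random.Generator) -> None:
        """Receive a finished child's best (x, f); default is stateless."""


class RandomGenerator(Generator):
    """Uniformly random point in the bound box."""

    def __init__(self, bounds: Bounds):
        self.bounds = bounds

    def ask(self, log: CentralLog, rng: np.random.Generator) -> np.ndarray:
        return self.bounds.uniform(rng)


class IncumbentGenerator(Generator):
    """The manager's best point so far; uniform random before any record."""

    def __init__(self, bounds: Bounds):
        self.bounds = bounds

    def ask(self, log: CentralLog, rng: np.random.Generator) -> np.ndarray:
        best = log.overall_best
        if best is None:
            return self.bounds.uniform(rng)
        return best.x.copy()


class BasinHoppingGenerator(Generator):
    """Monte-Carlo chain start generator (basin-hopping style).

    Keeps one accepted reference point. A finished child's result is
    Metropolis-accepted against the reference at fixed temperature ``T``
    (downhill always; uphill with probability exp(-df/T)); the next start is
    the reference displaced by a uniform step of at most ``stepsize`` per
    dimension, clipped to the box. Defaults T=0.8, stepsize=1 follow the
    classic cluster-optimization practice.
    """

    def __init__(self, bounds: Bounds, T: float = 0.8, stepsize: float = 1.0):
        if T <= 0 or stepsize <= 0:
            raise ValueError("T and stepsize must be positive")
        self.bounds = bounds
        self.T = float(T)
        self.stepsize = float(stepsize)
        self.chain_x: np.ndarray | None = None
        self.chain_f = math.inf
        #: (x, f, accepted) per tell, exportable alongside the central log
        self.history: list[tuple[np.ndarray, float, bool]] = []

    def accept(self, f_new: float, rng: np.random.Generator) -> bool:
        if f_new <= self.chain_f:
            return True
        return rng.uniform() < math.exp(-(f_new - self.chain_f) / self.T)

    def tell(self, x: np.ndarray, f: float, rng: np.random.Generator) -> None:
        took = self.chain_x is None or self.accept(f, rng)
        if took:
            self.chain_x = np.asarray(x, dtype=float).copy()
            self.chain_f = float(f)
        self.history.append((np.asarray(x, dtype=float).copy(), float(f), took))

    def ask(self, log: CentralLog, rng: np.random.Generator) -> np.ndarray:
        if self.chain_x is None:
            return self.bounds.uniform(rng)
        step = rng.uniform(-self.stepsize, self.stepsize, size=self.bounds.dimension)
        return self.bounds.clip(self.chain_x + step)


class AnnealingGenerator(Generator):
    """Annealing chain start generator with temperature restarts.

    The visiting temperature follows the generalized-annealing schedule

        T_m = initial_temp * (2^(q-1) - 1) / ((1 + m)^(q-1) - 1)

    with visiting parameter ``q`` (default 2.62) and ``m`` the number of
    accepted tell() events since the last restart. Acceptance is Metropolis
    at the current temperature. Displacements are heavy-tailed (Cauchy)
    with scale proportional to the current-to-initial temperature ratio, so
    a hot chain takes long jumps. When T / initial_temp drops below
    ``restart_temp_ratio`` the temperature resets and the chain point
    re-randomizes uniformly.
    """

    def __init__(
        self,
        bounds: Bounds,
        initial_temp: float = 50_000.0,
        restart_temp_ratio: float = 0.01,
        visit: float = 2.62,
        step_scale: float | None = None,
    ):
        if initial_temp <= 0:
            raise ValueError("initial_temp must be positive")
        if not 0 < restart_temp_ratio < 1:
            raise ValueError("restart_temp_ratio must be in (0, 1)")
        self.bounds = bounds
        self.initial_temp = float(initial_temp)
        self.restart_temp_ratio = float(restart_temp_ratio)
        self.visit = float(visit)
        # full-step scale when the chain is at the initial temperature
        self.step_scale = (
            float(np.mean(bounds.widths)) / 2.0 if step_scale is None else step_scale
        )
        self.m = 0
        self.chain_x: np.ndarray | None = None
        self.chain_f = math.inf
        self.history: list[tuple[np.ndarray, float, bool]] = []

    @property
    def temperature(self) -> float:
        qm1 = self.visit - 1.0
        return self.initial_temp * (2.0**qm1 - 1.0) / ((1.0 + self.m) ** qm1 - 1.0 + 1e-300) if self.m > 0 else self.initial_temp

    def tell(self, x: np.ndarray, f: float, rng: np.random.Generator) -> None:
        T = self.temperature
        took = (
            self.chain_x is None
            or f <= self.chain_f
            or rng.uniform() < math.exp(-(f - self.chain_f) / T)
        )
        if took:
            self.chain_x = np.asarray(x, dtype=float).copy()
            self.chain_f = float(f)
        self.history.append((np.asarray(x, dtype=float).copy(), float(f), took))
        self.m += 1
        if self.temperature / self.initial_temp < self.restart_temp_ratio:
            # restart: reheat and re-randomize the chain point
            self.m = 0
            self.chain_x = self.bounds.uniform(rng)
            self.chain_f = math.inf

    def ask(self, log: CentralLog, rng: np.random.Generator) -> np.ndarray:
        if self.chain_x is None:
            return self.bounds.uniform(rng)
        scale = self.step_scale * self.temperature / self.initial_temp
        step = scale * rng.standard_cauchy(self.bounds.dimension)
        return self.bounds.clip(self.chain_x + step)


def make_generator(kind: str, bounds: Bounds, **kwargs) -> Generator:
    kinds = {
        "random": RandomGenerator,
        "incumbent": IncumbentGenerator,
        "bh_step": BasinHoppingGenerator,
        "da_step": AnnealingGenerator,
    }
    try:
        cls = kinds[kind]
    except KeyError:
        raise ValueError(f"unknown generator kind {kind!r}") from None
    return cls(bounds, **kwargs)


# ---------------------------------------------------------------------------


@dataclass
class ManagerSnapshot:
    """What a selector may condition on: coarse run progress."""

    children_started: int
    total_evals: int
    eval_budget: float


class Selector:
    def select(self, snapshot: ManagerSnapshot) -> ChildConfig:
        raise NotImplementedError


class SingleSelector(Selector):
    def __init__(self, config: ChildConfig):
        self.config = config

    def select(self, snapshot: ManagerSnapshot) -> ChildConfig:
        return self.config


class RoundRobinSelector(Selector):
    """Cycle through the pool in spawn order: A, B, A, B, ..."""

    def __init__(self, pool: Sequence[ChildConfig]):
        if not pool:
            raise ValueError("selector pool must be non-empty")
        self.pool = list(pool)

    def select(self, snapshot: ManagerSnapshot) -> ChildConfig:
        return self.pool[snapshot.children_started % len(self.pool)]


class StagedSelector(Selector):
    """Early/late two-stage pool: switch irreversibly at a budget fraction."""

    def __init__(
        self,
        early: ChildConfig,
        late: ChildConfig,
        switch_at_fraction: float = 0.5,
    ):
        if not 0 < switch_at_fraction < 1:
            raise ValueError("switch_at_fraction must be in (0, 1)")
        self.early = early
        self.late = late
        self.switch_at_fraction = switch_at_fraction
        self._switched = False

    def select(self, snapshot: ManagerSnapshot) -> ChildConfig:
        if not self._switched and snapshot.eval_budget and (
            snapshot.total_evals / snapshot.eval_budget >= self.switch_at_fraction
        ):
            self._switched = True
        return self.late if self._switched else self.early
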