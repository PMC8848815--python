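"""Serial-vs-managed bout harness.

A *bout* links an unmanaged multi-start run to a managed run through the
evaluation budget: ``n_s`` serial children run to natural convergence with
no limits, the sum of the evaluations they used becomes the managed run's
budget, and the side with the lower final value wins. Both sides use the
same child optimizer template, so any performance difference is
attributable to management (termination, replacement, information sharing).
A set is ``n_b`` bouts of one configuration; win percentage is the fraction
of bouts the managed side won.

The serial leg can also be run as *sequential nudging*: each successive
serial child starts at, and injects, the best point found by its
predecessors. That is not a practical strategy, but isolates the effect of
concurrent information sharing from the nudging algorithm itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .core_log import CentralLog
from .generators import SingleSelector, make_generator
from .hunters import Hunter, Never
from .manager import CheckerSpec, ManagerConfig, ManagerResult, _child_seed
from .manager import run as run_managed
from .optimizers import ChildConfig, make_child
from .tasks import Task

__all__ = [
    "BoutConfig",
    "BoutResult",
    "SerialLegResult",
    "SetSummary",
    "run_serial_leg",
    "run_bout",
    "run_set",
    "summarize_set",
    "shift_scale",
    "best_eval_index_stats",
]

#: draw when the two final values agree to double precision (relative)
DRAW_RTOL = 1e-12

#: safety cap on a single serial child that fails to converge naturally
SERIAL_EVAL_CAP = 10_000_000


@dataclass
class SerialLegResult:
    best_x: np.ndarray
    best_f: float
    serial_evals_used: int
    per_run_minima: list[float]
    best_eval_index: int  # cumulative over the leg, 1-based


@dataclass
class BoutResult:
    serial_f: float
    serial_x: np.ndarray
    managed_f: float
    managed_x: np.ndarray
    serial_evals_used: int
    managed_evals_used: int
    outcome: str  # managed_win | serial_win | draw
    serial_best_eval_index: int
    managed_best_eval_index: int
    managed_children_started: int = 0
    managed_children_hunted: int = 0


@dataclass
class SetSummary:
    n_bouts: int
    wins: int
    draws: int
    losses: int
    win_percentage: float
    draw_percentage: float
    serial_minima: list[float]
    managed_minima: list[float]
    serial_minima_z: list[float]
    managed_minima_z: list[float]
    mean_serial_best_index: float
    mean_managed_best_index: float


@dataclass
class BoutConfig:
    """One serial-vs-managed contest.

    ``task_factory`` is called with a per-bout rng so tasks with randomized
    features (e.g. the deceptive function's minimizer placement) are fresh
    each bout. ``serial_mode`` is ``independent`` or ``sequential_ncma``.
    ``management_free`` configures the managed leg to be an exact replica of
    the serial leg (no hunting, no sharing, same seeds): the oracle limit in
    which every bout must be a draw.
    """

    task_factory: Callable[[np.random.Generator], Task]
    n_s: int = 10
    n_g: int = 4
    child: ChildConfig = field(default_factory=ChildConfig)
    serial_child: ChildConfig | None = None
    hunter: Hunter = field(default_factory=Never)
    generator_kind: str = "random"
    share_best: bool = False
    serial_mode: str = "independent"
    management_free: bool = False
    seed: int = 0
    fixed_budget: int | None = None  # checker-only bout variant

    def __post_init__(self) -> None:
        if self.serial_mode not in ("independent", "sequential_ncma"):
            raise ValueError(f"unknown serial_mode {self.serial_mode!r}")


def _spawn_rng(child_seed: int) -> np.random.Generator:
    # same derivation the manager uses for its spawn-time generator draws
    return np.random.default_rng(np.random.SeedSequence([child_seed, 0x53545254]))


def _serial_child_seed(seed: int, i: int) -> int:
    # decorrelated from the managed leg's per-ordinal seed stream
    return int(
        np.random.SeedSequence([seed, 0x5345, i]).generate_state(1)[0] % (2**31)
    )


def run_serial_leg(
    task: Task,
    child_template: ChildConfig,
    n_s: int,
    seed: int,
    sequential_ncma: bool = False,
    share_manager_seeds: bool = False,
) -> SerialLegResult:
    """Run ``n_s`` unmanaged children to natural convergence.

    Each child gets a fresh uniformly random start (sequential nudging
    children after the first start at the best point so far) and runs until
    its own convergence criterion fires; a safety cap guards non-convergent
    children. Evaluation counts are summed into the bout budget.

    ``share_manager_seeds`` makes child i use the exact seed the manager
    would give its i-th spawned child; the two legs are then replicas
    (the management-free limit). By default the legs draw from
    decorrelated seed streams so a bout compares independent samples.
    """
    total = 0
    best_x: np.ndarray | None = None
    best_f = math.inf
    best_index = 0
    minima: list[float] = []

    for i in range(n_s):
        child_seed = (
            _child_seed(seed, i) if share_manager_seeds else _serial_child_seed(seed, i)
        )
        rng = _spawn_rng(child_seed)
        cfg = replace(
            child_template,
            seed=child_seed,
            max_evals=min(
                child_template.max_evals or SERIAL_EVAL_CAP, SERIAL_EVAL_CAP
            ),
        )
        if sequential_ncma:
            cfg = replace(cfg, kind="ncma")
            if best_x is not None:
                start = best_x.copy()
                initial_candidate = (best_x, best_f)
            else:
                start = task.bounds.uniform(rng)
                initial_candidate = None
        else:
            start = task.bounds.uniform(rng)
            initial_candidate = None

        child = make_child(f"serial-{i}", task, cfg, start, initial_candidate)
        offset = total
        while not child.converged and not child.stopped:
            before = child.evals_used
            # cumulative 1-based leg index of each evaluation (push_interval 1)
            for j, (x, f, _) in enumerate(child.step()):
                if f < best_f:
                    best_f = f
                    best_x = np.asarray(x, dtype=float).copy()
                    best_index = offset + before + j + 1
            if child.evals_used >= cfg.max_evals:
                break
        total += child.evals_used
        minima.append(child.best_f)

    return SerialLegResult(
        best_x=best_x,
        best_f=best_f,
        serial_evals_used=total,
        per_run_minima=minima,
        best_eval_index=best_index,
    )


def run_bout(cfg: BoutConfig) -> BoutResult:
    """One budget-linked contest; returns the outcome and both legs' stats."""
    task_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x54]))
    task = cfg.task_factory(task_rng)

    serial_template = cfg.serial_child if cfg.serial_child is not None else cfg.child
    if cfg.fixed_budget is not None:
        serial_template = replace(
            serial_template, max_evals=cfg.fixed_budget // max(cfg.n_s, 1)
        )
    serial = run_serial_leg(
        task,
        serial_template,
        cfg.n_s,
        cfg.seed,
        sequential_ncma=cfg.serial_mode == "sequential_ncma",
        share_manager_seeds=cfg.management_free,
    )
    budget = cfg.fixed_budget if cfg.fixed_budget is not None else serial.serial_evals_used

    mgr_cfg = ManagerConfig(
        n_g=cfg.n_s if cfg.management_free else cfg.n_g,
        checkers=[CheckerSpec("evals_budget", budget)],
        selector=SingleSelector(cfg.child),
        generator=make_generator(cfg.generator_kind, task.bounds),
        hunter=Never() if cfg.management_free else cfg.hunter,
        share_best=False if cfg.management_free else cfg.share_best,
        seed=cfg.seed,
        max_children=cfg.n_s if cfg.management_free else None,
    )
    managed = run_managed(task, mgr_cfg)

    m_best = managed.incumbent
    managed_f = m_best.f if m_best is not None else math.inf
    managed_x = m_best.x if m_best is not None else np.full(task.dimension, np.nan)

    if abs(managed_f - serial.best_f) <= DRAW_RTOL * max(1.0, abs(serial.best_f)):
        outcome = "draw"
    elif managed_f < serial.best_f:
        outcome = "managed_win"
    else:
        outcome = "serial_win"

    return BoutResult(
        serial_f=serial.best_f,
        serial_x=serial.best_x,
        managed_f=managed_f,
        managed_x=managed_x,
        serial_evals_used=serial.serial_evals_used,
        managed_evals_used=managed.total_evals,
        outcome=outcome,
        serial_best_eval_index=serial.best_eval_index,
        managed_best_eval_index=m_best.eval_index if m_best is not None else 0,
        managed_children_started=managed.children_started,
        managed_children_hunted=managed.children_hunted,
    )


def run_set(cfg: BoutConfig, n_b: int) -> list[BoutResult]:
    """Run ``n_b`` bouts of one configuration with per-bout derived seeds."""
    bouts = []
    for b in range(n_b):
        bout_seed = _child_seed(cfg.seed, 1000 + b)
        bouts.append(run_bout(replace(cfg, seed=bout_seed)))
    return bouts


def _zscore(values: Sequence[float]) -> list[float]:
    arr = np.asarray(values, dtype=float)
    sd = arr.std()
    if sd == 0:
        return [0.0] * arr.size
    return list((arr - arr.mean()) / sd)


def summarize_set(bouts: Sequence[BoutResult]) -> SetSummary:
    """Aggregate one set: win/draw/loss counts and normalized minima.

    Minima are z-scored over the pooled serial+managed values of the set so
    that sets on different functions can be compared on one axis.
    """
    if not bouts:
        raise ValueError("need at least one bout")
    wins = sum(b.outcome == "managed_win" for b in bouts)
    draws = sum(b.outcome == "draw" for b in bouts)
    losses = sum(b.outcome == "serial_win" for b in bouts)
    serial = [b.serial_f for b in bouts]
    managed = [b.managed_f for b in bouts]
    pooled = np.asarray(serial + managed, dtype=float)
    mu, sd = pooled.mean(), pooled.std()
    sd = sd if sd > 0 else 1.0
    return SetSummary(
        n_bouts=len(bouts),
        wins=wins,
        draws=draws,
        losses=losses,
        win_percentage=100.0 * wins / len(bouts),
        draw_percentage=100.0 * draws / len(bouts),
        serial_minima=serial,
        managed_minima=managed,
        serial_minima_z=list((np.asarray(serial) - mu) / sd),
        managed_minima_z=list((np.asarray(managed) - mu) / sd),
        mean_serial_best_index=float(
            np.mean([b.serial_best_eval_index for b in bouts])
        ),
        mean_managed_best_index=float(
            np.mean([b.managed_best_eval_index for b in bouts])
        ),
    )


def shift_scale(f: float, f_global_min: float) -> float:
    """Shift-scale normalization ``(f - f_min) / |f_min|``; 0 at the optimum."""
    if f_global_min == 0:
        raise ValueError("f_global_min must be nonzero")
    return (f - f_global_min) / abs(f_global_min)


def best_eval_index_stats(bouts: Sequence[BoutResult]) -> dict:
    """Mean and stdev of the evaluation index of each side's best point."""
    s = np.asarray([b.serial_best_eval_index for b in bouts], dtype=float)
    m = np.asarray([b.managed_best_eval_index for b in bouts], dtype=float)
    return {
        "serial_mean": float(s.mean()),
        "serial_std": float(s.std()),
        "managed_mean": float(m.mean()),
        "managed_std": float(m.std()),
    }
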