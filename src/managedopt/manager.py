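"""The supervising manager: spawn, monitor, share, hunt, stop.

Each manager cycle: (1) stop if any checker fires; (2) fill free child slots
up to ``n_g`` while budget remains (a new child is not started when the
remaining budget cannot cover one full population iteration); (3) give every
alive child one optimizer iteration and drain its pushed evaluations into
the central log; (4) broadcast the incumbent to injection-capable children
when it improved; (5) retire naturally converged children and evaluate the
hunter tree against every other alive child — never against the child
currently holding the overall best.

Children are scheduled round-robin, one iteration per cycle, in spawn
order. This synchronous scheduler makes every run a pure function of
(task, config, master seed).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Hashable

import numpy as np

from .cmaes import default_population_size
from .core_log import CentralLog, Incumbent
from .generators import Generator, ManagerSnapshot, Selector
from .hunters import Hunter, HunterContext, Never
from .optimizers import ChildConfig, make_child
from .tasks import Task

__all__ = [
    "CheckerSpec",
    "ManagerConfig",
    "ManagerResult",
    "run",
]


@dataclass(frozen=True)
class CheckerSpec:
    """Manager-level stop condition.

    kinds: ``evals_budget`` (threshold = total evaluations),
    ``target_value`` (stop once the incumbent reaches the threshold),
    ``max_local_searches`` (threshold = number of children started; used to
    cap the count of local searches in local-search-child strategies),
    ``wall_time`` (threshold = seconds).
    """

    kind: str
    threshold: float

    def __post_init__(self) -> None:
        if self.kind not in (
            "evals_budget",
            "target_value",
            "max_local_searches",
            "wall_time",
        ):
            raise ValueError(f"unknown checker kind {self.kind!r}")


@dataclass
class ManagerConfig:
    n_g: int
    checkers: list[CheckerSpec]
    selector: Selector
    generator: Generator
    hunter: Hunter = field(default_factory=Never)
    share_best: bool = True
    seed: int = 0
    max_children: int | None = None

    def __post_init__(self) -> None:
        if self.n_g < 1:
            raise ValueError("n_g must be >= 1")
        if not self.checkers:
            raise ValueError("at least one checker is required")

    @property
    def eval_budget(self) -> float:
        for c in self.checkers:
            if c.kind == "evals_budget":
                return c.threshold
        return math.inf


@dataclass
class ManagerResult:
    incumbent: Incumbent | None
    total_evals: int
    children_started: int
    children_hunted: int
    log: CentralLog
    end_reasons: dict[Hashable, str]
    stop_reason: str = ""
    progress: list[str] = field(default_factory=list)


def _child_seed(master_seed: int, ordinal: int) -> int:
    """Deterministic per-child seed from the master seed and spawn ordinal."""
    return int(
        np.random.SeedSequence([master_seed, ordinal]).generate_state(1)[0] % (2**31)
    )


def run(task: Task, cfg: ManagerConfig) -> ManagerResult:
    """Run a managed optimization of ``task`` under ``cfg``."""
    log = CentralLog(task.bounds)
    hunter_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x48]))
    gen_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x47]))
    budget = cfg.eval_budget
    start_time = time.monotonic()

    alive: list = []  # child objects, in spawn order
    end_reasons: dict[Hashable, str] = {}
    total_evals = 0
    children_started = 0
    children_hunted = 0
    stop_reason = ""
    progress: list[str] = []
    cycle = 0

    def checker_fired() -> str:
        for c in cfg.checkers:
            if c.kind == "evals_budget" and total_evals >= c.threshold:
                return "evals_budget"
            if c.kind == "target_value":
                best = log.overall_best
                if best is not None and best.f <= c.threshold:
                    return "target_value"
            if c.kind == "max_local_searches" and children_started >= c.threshold:
                # fires only once every started search has finished
                if not alive:
                    return "max_local_searches"
            if c.kind == "wall_time" and time.monotonic() - start_time >= c.threshold:
                return "wall_time"
        return ""

    def spawn_allowed() -> bool:
        if cfg.max_children is not None and children_started >= cfg.max_children:
            return False
        for c in cfg.checkers:
            if c.kind == "max_local_searches" and children_started >= c.threshold:
                return False
        remaining = budget - total_evals
        if not math.isfinite(budget):
            return True
        # throttle: don't start a child the budget can't give one iteration
        probe = cfg.selector.select(
            ManagerSnapshot(children_started, total_evals, budget)
        )
        lam = (
            probe.popsize
            if probe.popsize is not None
            else default_population_size(task.dimension)
        )
        need = lam if probe.kind in ("cma", "ncma") else 1
        return remaining >= need

    incumbent_broadcast_f = math.inf

    while True:
        stop_reason = checker_fired()
        if stop_reason:
            break

        # fill slots
        while len(alive) < cfg.n_g and spawn_allowed():
            snapshot = ManagerSnapshot(children_started, total_evals, budget)
            child_cfg = cfg.selector.select(snapshot)
            ordinal = children_started
            seed = (
                child_cfg.seed
                if child_cfg.seed is not None
                else _child_seed(cfg.seed, ordinal)
            )
            spawn_rng = np.random.default_rng(
                np.random.SeedSequence([seed, 0x53545254])
            )
            start = cfg.generator.ask(log, spawn_rng)
            child_cfg = ChildConfig(
                **{**child_cfg.__dict__, "seed": seed}
            )
            initial_candidate = None
            if child_cfg.kind == "ncma" and log.overall_best is not None:
                best = log.overall_best
                initial_candidate = (best.x, best.f)
            child = make_child(
                f"child-{ordinal}", task, child_cfg, start, initial_candidate
            )
            alive.append(child)
            children_started += 1
            progress.append(
                f"cycle {cycle}: spawned child-{ordinal} ({child_cfg.kind}, "
                f"seed {seed})"
            )

        if not alive:
            stop_reason = stop_reason or "budget_exhausted"
            break

        # one iteration per alive child, drained in spawn order
        for child in list(alive):
            before = child.evals_used
            try:
                pushed = child.step()
            except Exception:
                # a persistently failing task ends this child; the manager
                # carries on with the others
                total_evals += child.evals_used - before
                child.stop()
                alive.remove(child)
                end_reasons[child.child_id] = "error"
                continue
            total_evals += child.evals_used - before
            for x, f, extras in pushed:
                log.record(child.child_id, x, f, extras)

        # share the incumbent whenever it improved
        best = log.overall_best
        if cfg.share_best and best is not None and best.f < incumbent_broadcast_f:
            incumbent_broadcast_f = best.f
            for child in alive:
                child.tell_best(best.x, best.f)

        # retire naturally converged children
        for child in list(alive):
            if child.converged:
                alive.remove(child)
                end_reasons[child.child_id] = "converged"
                progress.append(
                    f"cycle {cycle}: {child.child_id} converged at f={child.best_f:.6g}"
                )
                if child.best_x is not None:
                    cfg.generator.tell(child.best_x, child.best_f, gen_rng)

        # hunt: never the child holding the overall best
        if alive and not isinstance(cfg.hunter, Never):
            best = log.overall_best
            alive_ids = [c.child_id for c in alive]
            draw_cache: dict = {}
            for child in list(alive):
                if not log.has_child(child.child_id):
                    continue
                if (
                    best is not None
                    and log.per_child_best(child.child_id).f <= best.f
                ):
                    continue  # best-holder is immune
                ctx = HunterContext(
                    log=log,
                    victim_id=child.child_id,
                    alive_ids=alive_ids,
                    bounds=task.bounds,
                    rng=hunter_rng,
                    draw_cache=draw_cache,
                )
                if cfg.hunter(ctx):
                    child.stop()
                    alive.remove(child)
                    end_reasons[child.child_id] = "hunted"
                    children_hunted += 1
                    progress.append(
                        f"cycle {cycle}: hunted {child.child_id} at "
                        f"f={child.best_f:.6g} (best {best.f:.6g})"
                    )
                    if child.best_x is not None:
                        cfg.generator.tell(child.best_x, child.best_f, gen_rng)

        cycle += 1

    for child in alive:
        child.stop()
        end_reasons[child.child_id] = "budget_stop"
    progress.append(f"stopped: {stop_reason} after {total_evals} evaluations")

    return ManagerResult(
        incumbent=log.overall_best,
        total_evals=total_evals,
        children_started=children_started,
        children_hunted=children_hunted,
        log=log,
        end_reasons=end_reasons,
        stop_reason=stop_reason,
        progress=progress,
    )
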