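"""Termination predicates ("hunters") evaluated against the central log.

A hunter inspects a candidate victim's trajectory — never the child's
internal state — and returns True when the child should be shut down early.
Hunters compose into boolean trees (and/or) so that, e.g., the stock
template

    (EvaluationsUnmoving and ValueAnnealing) or BestUnmoving or ParameterDistance

terminates children that have entered their focus phase *and* sit well above
the current leader, or that have stopped improving, or that crowd another
child's basin. The manager guarantees that the child holding the overall
best value is never hunted, whatever the tree says.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from .core_log import Bounds, CentralLog

__all__ = [
    "HunterContext",
    "Hunter",
    "EvaluationsUnmoving",
    "ValueAnnealing",
    "BestUnmoving",
    "ParameterDistance",
    "AllOf",
    "AnyOf",
    "Never",
    "Always",
    "hunting_template",
    "ncma_hunting_template",
    "STRICT_PRESET",
    "LOOSE_PRESET",
]

#: guard against division by a near-zero reference value
_DELTA = 1e-12


@dataclass
class HunterContext:
    """Everything a hunter may read for one decision.

    ``draw_cache`` is cleared by the manager once per cycle so stochastic
    hunters draw at most once per cycle per leaf, making a combined tree a
    pure function of (log snapshot, seed) within the cycle.
    """

    log: CentralLog
    victim_id: Hashable
    alive_ids: Sequence[Hashable]
    bounds: Bounds
    rng: np.random.Generator
    draw_cache: dict = field(default_factory=dict)


class Hunter:
    """Base node of the hunter boolean tree."""

    def __call__(self, ctx: HunterContext) -> bool:
        raise NotImplementedError

    def __and__(self, other: "Hunter") -> "Hunter":
        return AllOf(self, other)

    def __or__(self, other: "Hunter") -> "Hunter":
        return AnyOf(self, other)


class AllOf(Hunter):
    def __init__(self, *children: Hunter):
        if not children:
            raise ValueError("AllOf needs at least one child hunter")
        self.children = children

    def __call__(self, ctx: HunterContext) -> bool:
        return all(c(ctx) for c in self.children)


class AnyOf(Hunter):
    def __init__(self, *children: Hunter):
        if not children:
            raise ValueError("AnyOf needs at least one child hunter")
        self.children = children

    def __call__(self, ctx: HunterContext) -> bool:
        return any(c(ctx) for c in self.children)


class Never(Hunter):
    """Constant False: hunting disabled (the management-free limit)."""

    def __call__(self, ctx: HunterContext) -> bool:
        return False


class Always(Hunter):
    """Constant True; useful for degenerate-configuration tests."""

    def __call__(self, ctx: HunterContext) -> bool:
        return True


class EvaluationsUnmoving(Hunter):
    """Fire when the victim's recent evaluations have stopped moving.

    True iff the standard deviation of the victim's last ``calls`` function
    values is below ``tol`` times the magnitude of its most recent value —
    the signature of an optimizer deep in its focus phase. Returns False
    while fewer than ``calls`` evaluations exist.
    """

    def __init__(self, calls: int, tol: float):
        if calls < 2:
            raise ValueError("calls must be >= 2")
        if tol <= 0:
            raise ValueError("tol must be positive")
        self.calls = int(calls)
        self.tol = float(tol)

    def __call__(self, ctx: HunterContext) -> bool:
        if ctx.log.n_evals(ctx.victim_id) < self.calls:
            return False
        vals = ctx.log.trailing_values(ctx.victim_id, self.calls)
        return bool(np.std(vals) < self.tol * abs(vals[-1]))


class ValueAnnealing(Hunter):
    """Stochastic kill whose probability grows with the gap to the leader.

    With the victim's best value f_v and the lowest alive best f_b, the
    relative excess is r = (f_v - f_b) / max(|f_b|, delta) and the kill
    probability is P(r) = 1 - (1 - med_kill_chance)^r: the unique
    exponential-family curve with P(0) = 0 and P(1) = med_kill_chance (a
    victim exactly twice the leader is killed with probability
    ``med_kill_chance``). Children close to the leader are thus spared —
    they may yet become the best.
    """

    def __init__(self, med_kill_chance: float):
        if not 0 < med_kill_chance < 1:
            raise ValueError("med_kill_chance must be in (0, 1)")
        self.med_kill_chance = float(med_kill_chance)

    def kill_probability(self, r: float) -> float:
        r = max(0.0, r)
        return 1.0 - (1.0 - self.med_kill_chance) ** r

    def __call__(self, ctx: HunterContext) -> bool:
        if ctx.log.n_evals(ctx.victim_id) == 0:
            return False
        f_v = ctx.log.per_child_best(ctx.victim_id).f
        best = ctx.log.overall_best
        if best is None or f_v <= best.f:
            return False
        r = (f_v - best.f) / max(abs(best.f), _DELTA)
        key = ("value_annealing", id(self), ctx.victim_id)
        if key not in ctx.draw_cache:
            ctx.draw_cache[key] = float(ctx.rng.uniform())
        return ctx.draw_cache[key] < self.kill_probability(r)


class BestUnmoving(Hunter):
    """Fire when the victim's running best has stalled.

    With f_old the running best as it stood ``calls`` evaluations ago and
    f_new the current running best, fires iff the improvement
    (f_old - f_new) is below ``tol`` (a fraction) times max(|f_old|, delta).
    Catches children that explore forever without focusing.
    """

    def __init__(self, calls: int, tol: float):
        if calls < 2:
            raise ValueError("calls must be >= 2")
        if tol <= 0:
            raise ValueError("tol must be positive")
        self.calls = int(calls)
        self.tol = float(tol)

    def __call__(self, ctx: HunterContext) -> bool:
        if ctx.log.n_evals(ctx.victim_id) <= self.calls:
            return False
        f_old = ctx.log.running_best_at(ctx.victim_id, self.calls)
        f_new = ctx.log.per_child_best(ctx.victim_id).f
        return bool((f_old - f_new) < self.tol * max(abs(f_old), _DELTA))


class ParameterDistance(Hunter):
    """Fire when the victim's best point crowds another alive child's best.

    True iff the Euclidean distance between the victim's best point and any
    other alive child's best point is below ``relative_tolerance`` times the
    diameter of the bound box, and the victim is the worse-valued member of
    the close pair (the better member survives).
    """

    def __init__(self, relative_tolerance: float):
        if not 0 < relative_tolerance < 1:
            raise ValueError("relative_tolerance must be in (0, 1)")
        self.relative_tolerance = float(relative_tolerance)

    def __call__(self, ctx: HunterContext) -> bool:
        if ctx.log.n_evals(ctx.victim_id) == 0:
            return False
        victim = ctx.log.per_child_best(ctx.victim_id)
        threshold = self.relative_tolerance * ctx.bounds.diameter()
        for other_id in ctx.alive_ids:
            if other_id == ctx.victim_id or not ctx.log.has_child(other_id):
                continue
            if ctx.log.n_evals(other_id) == 0:
                continue
            other = ctx.log.per_child_best(other_id)
            if (
                np.linalg.norm(victim.x - other.x) < threshold
                and victim.f >= other.f
            ):
                return True
        return False


def hunting_template(
    eu_calls: int = 120,
    eu_tol: float = 1e-4,
    med_kill_chance: float = 0.25,
    bu_calls: int = 1200,
    bu_tol: float = 0.005,
    pd_rel_tol: float = 0.05,
) -> Hunter:
    """The stock combined hunter:

    (EvaluationsUnmoving and ValueAnnealing) or BestUnmoving or ParameterDistance

    Hunter parameters are task-dependent by nature; these defaults are this
    package's choices for the 20-dimensional benchmark boxes, expressed in
    evaluations and scaled to the children's natural run length (a CMA child
    at the d=20 default population size of 12 converges in roughly 500-800
    iterations). The EvaluationsUnmoving tolerance of 1e-4 marks focus
    onset — recent evaluations identical to about four digits — which is
    when terminating a child stops costing exploration.
    """
    return (
        (EvaluationsUnmoving(eu_calls, eu_tol) & ValueAnnealing(med_kill_chance))
        | BestUnmoving(bu_calls, bu_tol)
        | ParameterDistance(pd_rel_tol)
    )


def ncma_hunting_template(
    eu_calls: int = 120,
    eu_tol: float = 1e-4,
    bu_calls: int = 1200,
    bu_tol: float = 0.005,
) -> Hunter:
    """Hunting used with nudging children: the stochastic ValueAnnealing and
    the crowding ParameterDistance legs are dropped (nudged children are
    *meant* to converge near one another), leaving

        EvaluationsUnmoving or BestUnmoving
    """
    return EvaluationsUnmoving(eu_calls, eu_tol) | BestUnmoving(bu_calls, bu_tol)


#: Named presets: "strict" terminates children as soon as they appear to
#: focus; "loose" lets them refine well into the focus phase.
STRICT_PRESET = dict(eu_calls=60, eu_tol=1e-3, bu_calls=600, bu_tol=0.01)
LOOSE_PRESET = dict(eu_calls=360, eu_tol=1e-7, bu_calls=3600, bu_tol=0.001)
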