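"""Declarative run configuration: YAML in, validated objects out.

A run file has up to five blocks::

    task:     {name: schwefel, dimension: 20}
    manager:  {n_g: 4, share_best: true, generator: {kind: random},
               checkers: [{kind: evals_budget, threshold: 50000}],
               hunter: {any: [...]}}
    children: [{kind: cma, tolfun: 1.0e-11}]
    bout:     {n_s: 10, n_g: 4, n_b: 10, generator: random, share_best: false}
    seed:     1
    output_dir: out

Every defaulted field is echoed into the output manifest, and a manifest can
be loaded back as a config (lossless round trip), so a finished run is fully
replayable from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .core_log import Bounds
from .generators import Selector, SingleSelector, RoundRobinSelector, make_generator
from .hunters import (
    AllOf,
    AnyOf,
    BestUnmoving,
    EvaluationsUnmoving,
    Hunter,
    Never,
    ParameterDistance,
    ValueAnnealing,
)
from .manager import CheckerSpec, ManagerConfig
from .optimizers import ChildConfig
from .tasks import (
    Task,
    deceptive_task,
    lj_cluster_task,
    rastrigin_task,
    schwefel_task,
    shubert4_task,
    trap_task,
)

__all__ = ["ConfigError", "load_config", "build_task", "build_hunter", "manifest"]


class ConfigError(ValueError):
    """Raised with the offending field name when a config does not validate."""


_TASKS = {
    "schwefel": lambda p, rng: schwefel_task(int(p.get("dimension", 20))),
    "rastrigin": lambda p, rng: rastrigin_task(int(p.get("dimension", 66))),
    "deceptive": lambda p, rng: deceptive_task(
        int(p.get("dimension", 20)),
        p.get("min_location"),
        rng,
    ),
    "shubert4": lambda p, rng: shubert4_task(),
    "trap": lambda p, rng: trap_task(),
    "lj_cluster": lambda p, rng: lj_cluster_task(
        int(p["n_particles"]), int(p.get("space_dim", 3))
    ),
}

_HUNTER_LEAVES = {
    "evaluations_unmoving": lambda p: EvaluationsUnmoving(p["calls"], p["tol"]),
    "value_annealing": lambda p: ValueAnnealing(p["med_kill_chance"]),
    "best_unmoving": lambda p: BestUnmoving(p["calls"], p["tol"]),
    "parameter_distance": lambda p: ParameterDistance(p["relative_tolerance"]),
}

_CHILD_FIELDS = {f.name for f in dataclasses.fields(ChildConfig)}


def load_config(path) -> dict:
    """Load and validate a YAML run configuration; returns the raw mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration root must be a mapping")
    if "task" not in raw:
        raise ConfigError("missing required block: task")
    if not isinstance(raw["task"], Mapping) or "name" not in raw["task"]:
        raise ConfigError("task block must contain a name")
    if raw["task"]["name"] not in _TASKS:
        raise ConfigError(
            f"unknown task name {raw['task']['name']!r}; "
            f"choose from {sorted(_TASKS)}"
        )
    raw.setdefault("seed", 0)
    raw.setdefault("output_dir", "managedopt-out")
    for child in raw.get("children", []):
        unknown = set(child) - _CHILD_FIELDS
        if unknown:
            raise ConfigError(f"unknown child fields: {sorted(unknown)}")
    return dict(raw)


def build_task(block: Mapping, rng: np.random.Generator) -> Task:
    params = {k: v for k, v in block.items() if k != "name"}
    return _TASKS[block["name"]](params, rng)


def build_hunter(block: Mapping | None) -> Hunter:
    """Build a hunter boolean tree from nested any/all lists of leaf specs."""
    if block is None:
        return Never()
    if not isinstance(block, Mapping) or len(block) != 1:
        raise ConfigError(
            "hunter node must be a single-key mapping: any, all, or a leaf name"
        )
    (key, value), = block.items()
    if key == "any":
        return AnyOf(*[build_hunter(v) for v in value])
    if key == "all":
        return AllOf(*[build_hunter(v) for v in value])
    if key in _HUNTER_LEAVES:
        try:
            return _HUNTER_LEAVES[key](value)
        except KeyError as e:
            raise ConfigError(f"hunter leaf {key!r} missing parameter {e}") from None
    raise ConfigError(f"unknown hunter node {key!r}")


def build_children(raw: Mapping) -> list[ChildConfig]:
    blocks = raw.get("children") or [{}]
    return [ChildConfig(**b) for b in blocks]


def build_selector(children: list[ChildConfig]) -> Selector:
    if len(children) == 1:
        return SingleSelector(children[0])
    return RoundRobinSelector(children)


def build_manager_config(raw: Mapping, task: Task) -> ManagerConfig:
    block = raw.get("manager", {})
    checkers = [
        CheckerSpec(c["kind"], c["threshold"]) for c in block.get("checkers", [])
    ]
    if not checkers:
        checkers = [CheckerSpec("evals_budget", block.get("eval_budget", 100_000))]
    gen_block = dict(block.get("generator", {"kind": "random"}))
    generator = make_generator(gen_block.pop("kind", "random"), task.bounds, **gen_block)
    children = build_children(raw)
    return ManagerConfig(
        n_g=int(block.get("n_g", 2)),
        checkers=checkers,
        selector=build_selector(children),
        generator=generator,
        hunter=build_hunter(block.get("hunter")),
        share_best=bool(block.get("share_best", True)),
        seed=int(raw.get("seed", 0)),
    )


def manifest(raw: Mapping, result=None, extra: Mapping | None = None) -> dict:
    """The JSON-serializable echo of a run: config with all defaults applied."""
    doc: dict[str, Any] = {
        "schema": "managedopt/run-manifest/1",
        "config": _jsonable(dict(raw)),
    }
    if result is not None:
        inc = result.incumbent
        doc["result"] = {
            "incumbent_f": None if inc is None else inc.f,
            "incumbent_x": None if inc is None else list(inc.x),
            "incumbent_eval_index": None if inc is None else inc.eval_index,
            "total_evals": result.total_evals,
            "children_started": result.children_started,
            "children_hunted": result.children_hunted,
            "stop_reason": result.stop_reason,
            "end_reasons": {str(k): v for k, v in result.end_reasons.items()},
        }
    if extra:
        doc.update(_jsonable(dict(extra)))
    return doc


def write_manifest(doc: Mapping, path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
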