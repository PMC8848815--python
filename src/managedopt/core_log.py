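"""Central evaluation log shared by the manager, hunters, and analyses.

Every function evaluation performed by any child optimizer is (optionally
thinned, see ``push_interval``) appended to a single :class:`CentralLog`.
The log is the only state hunters and generators are allowed to read, which
makes termination decisions reproducible from the stored trajectory alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Hashable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["Bounds", "EvaluationRecord", "Incumbent", "CentralLog"]


@dataclass(frozen=True)
class Bounds:
    """A finite box ``lower[i] <= x[i] <= upper[i]``.

    Parameters are kept as float arrays; construction validates that the box
    is non-degenerate (``lower < upper`` elementwise) and finite.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, lower: Iterable[float], upper: Iterable[float]):
        lo = np.asarray(lower, dtype=float)
        up = np.asarray(upper, dtype=float)
        if lo.shape != up.shape or lo.ndim != 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(up))):
            raise ValueError("bounds must be finite")
        if not np.all(lo < up):
            raise ValueError("lower bounds must be strictly below upper bounds")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @property
    def dimension(self) -> int:
        return self.lower.size

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    def diameter(self) -> float:
        """Euclidean distance between the two most distant corners."""
        return float(np.linalg.norm(self.widths))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray, atol: float = 0.0) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol))

    def uniform(self, rng: np.random.Generator, n: int | None = None) -> np.ndarray:
        if n is None:
            return rng.uniform(self.lower, self.upper)
        return rng.uniform(self.lower, self.upper, size=(n, self.dimension))


@dataclass(frozen=True)
class EvaluationRecord:
    """One function evaluation as received by the manager.

    ``eval_index`` is global and 1-based, assigned in order of receipt at the
    manager (not by child-side clocks) so that budget accounting is
    deterministic for a fixed interleaving.
    """

    child_id: Hashable
    eval_index: int
    x: np.ndarray
    f: float
    extras: Mapping[str, Any] | None = None


@dataclass(frozen=True)
class Incumbent:
    """Best point seen so far and the evaluation index first attaining it."""

    x: np.ndarray
    f: float
    eval_index: int


class _ChildTrace:
    __slots__ = ("f", "eval_indices", "best_x", "best_f", "best_index")

    def __init__(self) -> None:
        self.f: list[float] = []
        self.eval_indices: list[int] = []
        self.best_x: np.ndarray | None = None
        self.best_f: float = np.inf
        self.best_index: int = -1


class CentralLog:
    """Append-only store of every pushed evaluation, queryable per child.

    Maintains, incrementally, the per-child best points and the manager-wide
    incumbent. Ties keep the earlier record so the "evaluation index of the
    best" statistic is unique.
    """

    def __init__(self, bounds: Bounds | None = None):
        self.bounds = bounds
        self.records: list[EvaluationRecord] = []
        self._children: dict[Hashable, _ChildTrace] = {}
        self._incumbent: Incumbent | None = None

    # -- write side ---------------------------------------------------------

    def record(
        self,
        child_id: Hashable,
        x: np.ndarray,
        f: float,
        extras: Mapping[str, Any] | None = None,
    ) -> EvaluationRecord:
        """Append one evaluation; returns the stored record.

        The global evaluation index is assigned here, in order of receipt.
        """
        x = np.asarray(x, dtype=float)
        if self.bounds is not None and x.size != self.bounds.dimension:
            raise ValueError(
                f"evaluation has dimension {x.size}, log expects {self.bounds.dimension}"
            )
        f = float(f)
        rec = EvaluationRecord(child_id, len(self.records) + 1, x, f, extras)
        self.records.append(rec)

        trace = self._children.setdefault(child_id, _ChildTrace())
        trace.f.append(f)
        trace.eval_indices.append(rec.eval_index)
        if f < trace.best_f:
            trace.best_f = f
            trace.best_x = x
            trace.best_index = rec.eval_index
        if self._incumbent is None or f < self._incumbent.f:
            self._incumbent = Incumbent(x, f, rec.eval_index)
        return rec

    # -- read side ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    @property
    def overall_best(self) -> Incumbent | None:
        return self._incumbent

    @property
    def child_ids(self) -> list[Hashable]:
        return list(self._children)

    def has_child(self, child_id: Hashable) -> bool:
        return child_id in self._children

    def n_evals(self, child_id: Hashable) -> int:
        return len(self._trace(child_id).f)

    def per_child_best(self, child_id: Hashable) -> Incumbent:
        trace = self._trace(child_id)
        if trace.best_x is None:
            raise KeyError(f"child {child_id!r} has no records")
        return Incumbent(trace.best_x, trace.best_f, trace.best_index)

    def trailing_values(self, child_id: Hashable, calls: int) -> np.ndarray:
        """The up-to-``calls`` most recent f values for a child, newest last."""
        if calls < 0:
            raise ValueError("calls must be non-negative")
        trace = self._trace(child_id)
        if calls == 0:
            return np.empty(0)
        return np.asarray(trace.f[-calls:], dtype=float)

    def best_trajectory(self, child_id: Hashable) -> list[tuple[int, float]]:
        """Per-child running best, as (global eval_index, best-so-far f)."""
        trace = self._trace(child_id)
        return list(zip(trace.eval_indices, np.minimum.accumulate(trace.f)))

    def running_best_at(self, child_id: Hashable, evals_ago: int) -> float:
        """Running best f as it stood ``evals_ago`` evaluations earlier.

        ``evals_ago == 0`` is the current best. Used by the BestUnmoving hunter.
        """
        trace = self._trace(child_id)
        cut = len(trace.f) - evals_ago
        if cut < 1:
            raise ValueError("not enough history")
        return float(min(trace.f[:cut]))

    def _trace(self, child_id: Hashable) -> _ChildTrace:
        try:
            return self._children[child_id]
        except KeyError:
            raise KeyError(f"unknown child {child_id!r}") from None

    # -- export -------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        if not self.records:
            return pd.DataFrame(columns=["child_id", "eval_index", "f"])
        dim = self.records[0].x.size
        data = {
            "child_id": [r.child_id for r in self.records],
            "eval_index": [r.eval_index for r in self.records],
            "f": [r.f for r in self.records],
        }
        xs = np.vstack([r.x for r in self.records])
        for i in range(dim):
            data[f"x{i}"] = xs[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, path, dataset: str = "evaluations") -> None:
        """Binary export for large runs; one dataset of f/x plus child ids."""
        import h5py

        df = self.to_dataframe()
        with h5py.File(path, "w") as fh:
            grp = fh.create_group(dataset)
            grp.create_dataset(
                "child_id", data=np.asarray(df["child_id"].astype(str), dtype="S")
            )
            grp.create_dataset("eval_index", data=df["eval_index"].to_numpy())
            grp.create_dataset("f", data=df["f"].to_numpy())
            xcols = [c for c in df.columns if c.startswith("x")]
            if xcols:
                grp.create_dataset("x", data=df[xcols].to_numpy())
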