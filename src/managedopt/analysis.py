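"""Post-hoc landscape analyses on logged minima and reference points.

* degenerate-minima detection: distinct representatives of similar-valued,
  well-separated solutions;
* PCA eigenvalue comparison of a family of parameter sets against
  same-shape random-normal baselines (are the solutions correlated beyond
  chance?);
* per-parameter scans around a reference point;
* partial-solution scans: how informative is knowing k coordinates of the
  best solution?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_log import Bounds, CentralLog
from .tasks import Task

__all__ = [
    "DegenerateSpec",
    "find_degenerates",
    "pca_eigen_compare",
    "parameter_scan",
    "partial_solution_scan",
]


@dataclass(frozen=True)
class DegenerateSpec:
    """Value band plus a minimum mutual distance for distinctness.

    Two solutions are degenerate when their values both fall inside
    ``(f_lo, f_hi)`` but their parameter vectors are farther apart than
    ``radius``. Left unset, ``radius`` defaults to 5% of the bound-box
    diameter (the same convention the crowding hunter uses).
    """

    f_lo: float
    f_hi: float
    radius: float | None = None

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError("need f_lo < f_hi")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive")

    def resolve_radius(self, bounds: Bounds | None) -> float:
        if self.radius is not None:
            return self.radius
        if bounds is None:
            raise ValueError("radius not set and no bounds to derive it from")
        return 0.05 * bounds.diameter()


def find_degenerates(
    candidates: Sequence[tuple[np.ndarray, float]] | CentralLog,
    spec: DegenerateSpec,
    bounds: Bounds | None = None,
) -> list[tuple[np.ndarray, float]]:
    """Greedy representative selection of degenerate solutions.

    Candidates are sorted by value ascending; a candidate is accepted iff its
    value lies in the band and it is farther than the radius from every
    already-accepted representative. A :class:`CentralLog` may be passed
    directly, in which case each child's best point is the candidate pool.
    """
    if isinstance(candidates, CentralLog):
        bounds = bounds if bounds is not None else candidates.bounds
        pool = [
            (candidates.per_child_best(c).x, candidates.per_child_best(c).f)
            for c in candidates.child_ids
        ]
    else:
        pool = [(np.asarray(x, dtype=float), float(f)) for x, f in candidates]
    radius = spec.resolve_radius(bounds)

    accepted: list[tuple[np.ndarray, float]] = []
    for x, f in sorted(pool, key=lambda t: t[1]):
        if not (spec.f_lo < f < spec.f_hi):
            continue
        if all(np.linalg.norm(x - ax) > radius for ax, _ in accepted):
            accepted.append((x, f))
    return accepted


def degenerates_to_frame(reps: Sequence[tuple[np.ndarray, float]]) -> pd.DataFrame:
    """Representatives as a table with the value column first."""
    if not reps:
        return pd.DataFrame(columns=["f"])
    data = {"f": [f for _, f in reps]}
    X = np.vstack([x for x, _ in reps])
    for i in range(X.shape[1]):
        data[f"x{i}"] = X[:, i]
    return pd.DataFrame(data)


def pca_eigen_compare(
    sets: np.ndarray,
    n_random: int = 100,
    rng: np.random.Generator | None = None,
    scale_to_unit: bool = True,
    bounds: Bounds | None = None,
) -> dict:
    """Covariance eigenvalues of m parameter vectors vs random baselines.

    Returns the descending eigenvalues of the sets' covariance matrix plus
    the mean and stdev of the eigenvalue spectra of ``n_random`` same-shape
    standard-normal matrices. Parameter vectors are scaled into [0, 1] by
    the bounds before the decomposition when requested, so heterogeneous
    parameter units do not dominate the spectrum.
    """
    sets = np.asarray(sets, dtype=float)
    if sets.ndim != 2 or sets.shape[0] < 2:
        raise ValueError("need an (m, l) matrix with m >= 2 parameter vectors")
    if scale_to_unit and bounds is not None:
        sets = (sets - bounds.lower) / bounds.widths
    rng = rng if rng is not None else np.random.default_rng()

    eig = np.sort(np.linalg.eigvalsh(np.cov(sets, rowvar=False)))[::-1]
    m, l = sets.shape
    baseline = np.empty((n_random, l))
    for k in range(n_random):
        R = rng.standard_normal((m, l))
        baseline[k] = np.sort(np.linalg.eigvalsh(np.cov(R, rowvar=False)))[::-1]
    return {
        "eigenvalues": eig,
        "baseline_mean": baseline.mean(axis=0),
        "baseline_std": baseline.std(axis=0),
    }


def parameter_scan(
    task: Task,
    reference: np.ndarray,
    points_per_parameter: int = 100,
) -> pd.DataFrame:
    """One-at-a-time scans through the reference point.

    For each parameter i, the function is evaluated on an evenly spaced grid
    of ``points_per_parameter`` values from the lower to the upper bound,
    with every other parameter held at the reference. Long-format output:
    columns (parameter, value, f).
    """
    reference = np.asarray(reference, dtype=float)
    if not task.bounds.contains(reference):
        raise ValueError("reference point must lie within the task bounds")
    rows = []
    for i in range(task.dimension):
        grid = np.linspace(
            task.bounds.lower[i], task.bounds.upper[i], points_per_parameter
        )
        X = np.tile(reference, (points_per_parameter, 1))
        X[:, i] = grid
        f = task.batch(X)
        for v, fv in zip(grid, f):
            rows.append((i, float(v), float(fv)))
    return pd.DataFrame(rows, columns=["parameter", "value", "f"])


def partial_solution_scan(
    task: Task,
    best: np.ndarray,
    per_level: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """How informative are partially correct solutions?

    For each k = 1..d-1, draw ``per_level`` uniform random vectors and
    overwrite k randomly chosen coordinates with the best solution's values,
    then evaluate. On a well-behaved (e.g. separable) landscape the values
    fall as k grows; on a rugged one the noise swamps the trend — the
    diagnostic for whether solution injection can inform the search.
    Long-format output: columns (k, f); total rows per_level * (d - 1).
    """
    best = np.asarray(best, dtype=float)
    if not task.bounds.contains(best):
        raise ValueError("best point must lie within the task bounds")
    d = task.dimension
    if d < 2:
        raise ValueError("need dimension >= 2")
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    for k in range(1, d):
        X = task.bounds.uniform(rng, per_level)
        for r in range(per_level):
            idx = rng.choice(d, size=k, replace=False)
            X[r, idx] = best[idx]
        f = task.batch(X)
        rows.extend((k, float(v)) for v in f)
    return pd.DataFrame(rows, columns=["k", "f"])
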