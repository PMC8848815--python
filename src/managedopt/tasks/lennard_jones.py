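"""Lennard-Jones cluster energies with analytic gradients.

The optimization variable is the flattened (N, d) coordinate matrix, so an
N-particle cluster in d=3 is an N*d-dimensional problem. The energy surface
is invariant to rigid translations/rotations and particle permutation, hence
massively degenerate, and has steep near-singular walls wherever two
particles approach — a classic rugged global-optimization benchmark.
"""

from __future__ import annotations

import numpy as np

from ..core_log import Bounds
from .base import Task

__all__ = [
    "lj_energy",
    "lj_gradient",
    "lj_min_pair_distance",
    "lj_cluster_task",
    "read_xyz",
    "write_xyz",
]


def _pair_distances(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = X.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    diff = X[iu] - X[ju]
    r = np.linalg.norm(diff, axis=1)
    return iu, ju, r


def lj_energy(
    X: np.ndarray, epsilon: float = 1.0, sigma: float = 1.0
) -> float:
    """Total 12-6 pair energy ``4 eps sum_{i<j} [(sig/r)^12 - (sig/r)^6]``.

    Raises for coincident particles (the energy is not finite there).
    """
    X = np.asarray(X, dtype=float)
    _, _, r = _pair_distances(X)
    if np.any(r == 0.0):
        raise ValueError("coincident particles: Lennard-Jones energy is not finite")
    sr6 = (sigma / r) ** 6
    return float(4.0 * epsilon * np.sum(sr6 * sr6 - sr6))


def lj_min_pair_distance(X: np.ndarray) -> float:
    """Smallest pairwise distance; exposed as an extras channel so hunters or
    analyses can detect collapsing geometries."""
    _, _, r = _pair_distances(np.asarray(X, dtype=float))
    return float(np.min(r))


def lj_gradient(
    X: np.ndarray, epsilon: float = 1.0, sigma: float = 1.0
) -> np.ndarray:
    """Analytic dE/dX, shape (N, d). Net force (column sum) is zero."""
    X = np.asarray(X, dtype=float)
    iu, ju, r = _pair_distances(X)
    if np.any(r == 0.0):
        raise ValueError("coincident particles: Lennard-Jones gradient is not finite")
    diff = X[iu] - X[ju]
    sr6 = (sigma / r) ** 6
    # dE/dr for one pair = 4 eps (-12 sig^12/r^13 + 6 sig^6/r^7)
    dEdr_over_r = 4.0 * epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / (r * r)
    grad = np.zeros_like(X)
    contrib = dEdr_over_r[:, None] * diff
    np.add.at(grad, iu, contrib)
    np.add.at(grad, ju, -contrib)
    return grad


def lj_cluster_task(
    n_particles: int,
    space_dim: int = 3,
    epsilon: float = 1.0,
    sigma: float = 1.0,
) -> Task:
    """LJ cluster as a flat-vector task.

    The coordinate box has half-width ``0.75 * n_particles**(1/3) * sigma`` per
    coordinate, which keeps the enclosed density roughly constant as the
    cluster size grows; the known minimum-energy value is left unset (it is
    what the optimizers are after).
    """
    if n_particles < 2:
        raise ValueError("need at least two particles")
    if epsilon <= 0 or sigma <= 0:
        raise ValueError("epsilon and sigma must be positive")
    dim = n_particles * space_dim
    half = 0.75 * n_particles ** (1.0 / 3.0) * sigma
    b = Bounds([-half] * dim, [half] * dim)

    def _f(x: np.ndarray) -> float:
        return lj_energy(x.reshape(n_particles, space_dim), epsilon, sigma)

    def _g(x: np.ndarray) -> np.ndarray:
        return lj_gradient(x.reshape(n_particles, space_dim), epsilon, sigma).ravel()

    def _extras(x: np.ndarray) -> dict:
        return {"min_pair_distance": lj_min_pair_distance(x.reshape(n_particles, space_dim))}

    return Task(
        name=f"lj{n_particles}",
        bounds=b,
        evaluate=_f,
        gradient=_g,
        extras_fn=_extras,
    )


def write_xyz(path, X: np.ndarray, comment: str = "", element: str = "Ar") -> None:
    """Write one frame in plain XYZ (count line, comment line, element x y z)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    with open(path, "w") as fh:
        fh.write(f"{X.shape[0]}\n{comment}\n")
        for row in X:
            fh.write(element + " " + " ".join(f"{v:.10f}" for v in row) + "\n")


def read_xyz(path) -> np.ndarray:
    """Read the first frame of an XYZ file; returns the (N, d) coordinates."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].strip())
    coords = [
        [float(v) for v in line.split()[1:]] for line in lines[2 : 2 + n]
    ]
    return np.asarray(coords, dtype=float)
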