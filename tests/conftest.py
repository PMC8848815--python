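import numpy as np
import pytest

from managedopt import Bounds, ChildConfig
from managedopt.tasks import Task, schwefel_task


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def unit_box2():
    return Bounds([0.0, 0.0], [1.0, 1.0])


def quadratic_task(dimension: int = 3, vertex: float = 1.2) -> Task:
    """Convex bowl with a known vertex — the simplest oracle task."""
    b = Bounds([-5.0] * dimension, [5.0] * dimension)
    v = np.full(dimension, vertex)
    return Task(
        name="quadratic",
        bounds=b,
        evaluate=lambda x: float(np.sum((x - v) ** 2)),
        evaluate_batch=lambda X: np.sum((X - v) ** 2, axis=1),
        gradient=lambda x: 2.0 * (x - v),
        known_min_x=v.copy(),
        known_min_f=0.0,
    )


@pytest.fixture
def quadratic3():
    return quadratic_task(3)


@pytest.fixture
def schwefel5():
    return schwefel_task(5)


@pytest.fixture
def fast_child():
    return ChildConfig(kind="cma", tolfun=1e-9)
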