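import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from managedopt.tasks import (
    SCHWEFEL_XSTAR,
    TRAP_CORNERS,
    TrainingSetCost,
    deceptive,
    deceptive_task,
    lj_cluster_task,
    lj_energy,
    lj_gradient,
    rastrigin,
    read_training_set,
    read_xyz,
    schwefel,
    shubert4,
    shubert4_task,
    training_cost,
    trap,
    write_xyz,
)


def schwefel_1d_minimizer():
    """Independent 1-D oracle: dense grid + local refinement of the
    separable term 418.9829 - x sin(sqrt(|x|)) on [-500, 500]."""
    grid = np.linspace(-500, 500, 200_001)
    vals = 418.9829 - grid * np.sin(np.sqrt(np.abs(grid)))
    x0 = grid[np.argmin(vals)]
    res = minimize_scalar(
        lambda x: 418.9829 - x * np.sin(np.sqrt(abs(x))),
        bracket=(x0 - 0.1, x0, x0 + 0.1),
    )
    return float(res.x)


class TestSchwefel:
    def test_global_minimum_near_zero_at_known_minimizer(self):
        d = 20
        assert schwefel(np.full(d, SCHWEFEL_XSTAR)) <= 1e-3 * d

    def test_value_at_origin(self):
        assert schwefel(np.zeros(2)) == pytest.approx(837.9658)

    def test_one_d_oracle_minimizer_to_four_decimals(self):
        assert round(schwefel_1d_minimizer(), 4) == SCHWEFEL_XSTAR

    def test_negative_mirror_is_strictly_worse(self):
        # the runner-up basin sits far from the winner
        assert schwefel(np.array([-SCHWEFEL_XSTAR])) > schwefel(
            np.array([SCHWEFEL_XSTAR])
        ) + 100


class TestRastrigin:
    def test_origin_is_global_minimum(self):
        for d in (1, 5, 66):
            assert rastrigin(np.zeros(d)) == pytest.approx(0.0, abs=1e-12)

    def test_integer_lattice_value(self):
        assert rastrigin(np.array([1.0, 1.0])) == pytest.approx(2.0)

    def test_nonnegative(self, rng):
        X = rng.uniform(-5.12, 5.12, size=(1000, 4))
        assert all(rastrigin(x) >= 0 for x in X)


class TestDeceptive:
    def test_minimum_attained_at_custom_location(self, rng):
        for _ in range(3):
            alpha = rng.uniform(0.1, 0.9, size=5)
            assert deceptive(alpha, alpha) == pytest.approx(-1.0)

    def test_grid_oracle_locates_minimum_2d(self):
        alpha = np.array([0.37, 0.61])
        g = np.linspace(0, 1, 401)
        G1, G2 = np.meshgrid(g, g)
        vals = np.array(
            [
                deceptive(np.array([a, b]), alpha)
                for a, b in zip(G1.ravel(), G2.ravel())
            ]
        )
        k = np.argmin(vals)
        found = np.array([G1.ravel()[k], G2.ravel()[k]])
        assert np.allclose(found, alpha, atol=1 / 400 + 1e-12)

    def test_location_outside_box_rejected(self):
        with pytest.raises(ValueError):
            deceptive(np.array([0.5]), np.array([1.5]))

    def test_randomized_task_instances_differ(self):
        t1 = deceptive_task(3, rng=np.random.default_rng(1))
        t2 = deceptive_task(3, rng=np.random.default_rng(2))
        assert not np.allclose(t1.known_min_x, t2.known_min_x)
        assert t1(t1.known_min_x) == pytest.approx(-1.0)


class TestShubert4:
    def test_periodicity_along_each_dimension(self, rng):
        for _ in range(10):
            x = rng.uniform(-3, 3, size=4)
            for i in range(4):
                shifted = x.copy()
                shifted[i] += 2 * np.pi
                assert shubert4(shifted) == pytest.approx(shubert4(x), rel=1e-9)

    def test_degenerate_global_minima_distinct_locations(self):
        # scan the first two coordinates with the rest fixed at a per-axis
        # optimum: at least two separated near-global minimizers must appear
        g = np.linspace(-10, 10, 2001)
        j = np.arange(1.0, 6.0)
        h = np.sum(j * np.cos(np.outer(g, j + 1) + j), axis=1)
        x_min = g[np.argmin(h)]  # most negative factor
        x_max = g[np.argmax(h)]
        best = shubert4(np.array([x_min, x_max, x_max, x_max]))
        # periodic copy one cell away has the same value
        copy = shubert4(np.array([x_min + 2 * np.pi, x_max, x_max, x_max]))
        assert copy == pytest.approx(best, rel=1e-6)
        assert best < -39000

    def test_global_band(self):
        """Near-optimal degenerates live in the (-39303, -39000) band; the
        grid-estimated global value itself sits at the band's lower edge."""
        g = np.linspace(-10, 10, 4001)
        j = np.arange(1.0, 6.0)
        h = np.sum(j * np.cos(np.outer(g, j + 1) + j), axis=1)
        global_est = h.min() * h.max() ** 3
        assert -39320 < global_est < -39290
        # slightly perturbed minimizers fall inside the band
        perturbed = shubert4(
            np.array([g[np.argmin(h)] + 0.01] + [g[np.argmax(h)]] * 3)
        )
        assert -39303 < perturbed < -39000

    def test_wrong_dimension_rejected(self):
        with pytest.raises(ValueError):
            shubert4(np.zeros(3))


class TestLennardJones:
    def test_dimer_at_potential_minimum(self):
        r = 2 ** (1 / 6)
        X = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        assert lj_energy(X) == pytest.approx(-1.0, abs=1e-12)
        assert np.max(np.abs(lj_gradient(X))) < 1e-12

    def test_dimer_at_unit_distance_is_zero(self):
        X = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        assert lj_energy(X) == pytest.approx(0.0, abs=1e-12)

    def test_equilateral_trimer(self):
        r = 2 ** (1 / 6)
        X = np.array(
            [[0.0, 0.0, 0.0], [r, 0.0, 0.0], [r / 2, r * np.sqrt(3) / 2, 0.0]]
        )
        assert lj_energy(X) == pytest.approx(-3.0, abs=1e-10)

    def test_coincident_particles_rejected(self):
        X = np.zeros((2, 3))
        with pytest.raises(ValueError, match="coincident"):
            lj_energy(X)
        with pytest.raises(ValueError, match="coincident"):
            lj_gradient(X)

    def test_gradient_matches_finite_differences(self, rng):
        """Central finite differences as the independent gradient oracle."""
        from managedopt.tasks import lj_min_pair_distance

        h = 1e-6
        done = 0
        while done < 20:
            n = int(rng.integers(3, 11))
            X = rng.uniform(-2.0, 2.0, size=(n, 3))
            if lj_min_pair_distance(X) < 0.8:
                continue  # keep finite differences well-conditioned
            done += 1
            g = lj_gradient(X)
            fd = np.zeros_like(X)
            for i in range(n):
                for k in range(3):
                    Xp, Xm = X.copy(), X.copy()
                    Xp[i, k] += h
                    Xm[i, k] -= h
                    fd[i, k] = (lj_energy(Xp) - lj_energy(Xm)) / (2 * h)
            scale = max(1.0, np.max(np.abs(fd)))
            assert np.max(np.abs(g - fd)) / scale < 1e-5

    def test_rigid_motion_invariance(self, rng):
        from scipy.stats import special_ortho_group

        X = rng.uniform(-1, 1, size=(5, 3)) * 2.0
        e0 = lj_energy(X)
        for _ in range(100):
            R = special_ortho_group.rvs(3, random_state=rng)
            t = rng.uniform(-10, 10, size=3)
            assert abs(lj_energy(X @ R.T + t) - e0) <= 1e-9 * max(1, abs(e0))

    def test_translation_leaves_gradient_unchanged(self, rng):
        X = rng.uniform(-1, 1, size=(4, 3)) * 2.0
        g0 = lj_gradient(X)
        g1 = lj_gradient(X + np.array([3.0, -2.0, 7.0]))
        assert np.allclose(g0, g1, atol=1e-9)

    def test_net_force_is_zero(self, rng):
        X = rng.uniform(-1, 1, size=(6, 3)) * 2.0
        assert np.allclose(lj_gradient(X).sum(axis=0), 0.0, atol=1e-10)

    def test_cluster_task_dimension_and_extras(self):
        t = lj_cluster_task(10)
        assert t.dimension == 30
        x = t.bounds.uniform(np.random.default_rng(0))
        f, extras = t.evaluate_with_extras(x)
        assert "min_pair_distance" in extras
        assert extras["min_pair_distance"] > 0

    def test_xyz_roundtrip(self, tmp_path):
        X = np.random.default_rng(3).uniform(-2, 2, size=(4, 3))
        path = tmp_path / "cluster.xyz"
        write_xyz(path, X, comment="test frame")
        assert np.allclose(read_xyz(path), X, atol=1e-9)


class TestTrainingCost:
    def test_perfect_fit_costs_zero(self):
        ts = TrainingSetCost(
            y=[1.0, 2.0], w=[1.0, 1.0], sigma=[1.0, 1.0], model=lambda xi, p: p[xi]
        )
        assert training_cost(np.array([1.0, 2.0]), ts) == 0.0

    def test_direct_arithmetic_example(self):
        ts = TrainingSetCost(
            y=[1.0, 2.0], w=[1.0, 2.0], sigma=[1.0, 1.0], model=lambda xi, p: 0.0
        )
        assert training_cost(np.zeros(1), ts) == pytest.approx(17.0)

    def test_doubling_sigma_quarters_cost(self, rng):
        y = rng.normal(size=6)
        w = rng.uniform(0.5, 2, size=6)
        ts1 = TrainingSetCost(y=y, w=w, sigma=np.ones(6), model=lambda xi, p: 0.0)
        ts2 = TrainingSetCost(y=y, w=w, sigma=2 * np.ones(6), model=lambda xi, p: 0.0)
        p = np.zeros(1)
        assert training_cost(p, ts2) == pytest.approx(training_cost(p, ts1) / 4)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            TrainingSetCost(y=[1.0], w=[1.0], sigma=[0.0], model=lambda xi, p: 0.0)

    def test_matches_naive_loop_oracle(self, rng):
        n, l = 12, 3
        y = rng.normal(size=n)
        w = rng.uniform(0.1, 3, size=n)
        sig = rng.uniform(0.5, 2, size=n)
        inputs = list(rng.normal(size=n))

        def model(xi, p):
            return p[0] * xi + p[1] * xi**2 + p[2]

        ts = TrainingSetCost(y=y, w=w, sigma=sig, model=model, inputs=inputs)
        p = rng.normal(size=l)
        naive = sum(
            (w[i] * (y[i] - model(inputs[i], p)) / sig[i]) ** 2 for i in range(n)
        )
        assert training_cost(p, ts) == pytest.approx(naive, rel=1e-12)

    def test_csv_reader(self, tmp_path):
        path = tmp_path / "ts.csv"
        path.write_text("y,w,sigma\n1.0,1.0,1.0\n2.0,2.0,0.5\n")
        ts = read_training_set(path, model=lambda xi, p: 0.0)
        assert ts.n_items == 2
        assert training_cost(np.zeros(1), ts) == pytest.approx(1.0 + 64.0)


class TestTrap:
    @pytest.mark.parametrize("corner,value", TRAP_CORNERS)
    def test_corner_values_exact(self, corner, value):
        assert trap(np.array(corner)) == value

    def test_more_zeros_lower_value_but_global_at_ones(self):
        vals = [trap(np.array(c)) for c, _ in TRAP_CORNERS]
        assert vals[0] == 0.0  # all-ones corner is the global minimum
        # zero-corner ladder decreases as zeros accumulate
        assert vals[1] > vals[2] > vals[3] > vals[4] > vals[0]
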