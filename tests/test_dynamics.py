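import math

import numpy as np
import pytest

from pathmeasure import (
    NoiseHistory,
    Path,
    TimeGrid,
    map_path,
    ou_exact_step,
    positions_matrix,
    propagate,
    propagate_ensemble,
    recover_noise,
    sample_brownian_bridge,
    sample_noise,
    sample_ou_bridge,
    sample_paths,
)

from conftest import EPS, process


class TestTimeGrid:
    def test_duration_is_derived(self):
        g = TimeGrid(dt=0.1, n_steps=10)
        assert g.duration == pytest.approx(1.0)
        assert len(g.times()) == 11
        assert g.times()[-1] == pytest.approx(1.0)

    @pytest.mark.parametrize("dt,n", [(0.0, 10), (-1.0, 10), (0.1, 0), (math.nan, 5)])
    def test_invalid_grids_rejected(self, dt, n):
        with pytest.raises(ValueError):
            TimeGrid(dt=dt, n_steps=n)


class TestNoise:
    def test_reproducible_from_seed(self, grid):
        a = sample_noise(grid, 3, 7)
        b = sample_noise(grid, 3, 7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_prefix_stable_when_n_paths_grows(self, grid):
        a = sample_noise(grid, 2, 7)
        b = sample_noise(grid, 5, 7)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)

    def test_zero_paths_rejected(self, grid):
        with pytest.raises(ValueError):
            sample_noise(grid, 0, 1)

    def test_pooled_moments_are_standard_normal(self):
        grid = TimeGrid(dt=1e-2, n_steps=500)
        pooled = np.concatenate([n.values for n in sample_noise(grid, 10000, 11)])
        n = pooled.size
        assert abs(pooled.mean()) < 4 / math.sqrt(n)
        # chi-square sampling theory: SE of the sample variance is sqrt(2/n)
        assert abs(pooled.var(ddof=1) - 1.0) < 3 * math.sqrt(2.0 / n)

    def test_wrong_length_rejected(self, grid):
        with pytest.raises(ValueError):
            NoiseHistory(np.zeros(grid.n_steps + 3), grid)


class TestPropagate:
    def test_zero_noise_zero_force_is_constant(self, grid):
        noise = NoiseHistory(np.zeros(grid.n_steps), grid)
        path = propagate(process("zero"), grid, noise, 0.7)
        np.testing.assert_array_equal(path.positions, np.full(grid.n_steps + 1, 0.7))

    def test_deterministic_euler_with_constant_drift(self):
        grid = TimeGrid(dt=0.1, n_steps=10)
        noise = NoiseHistory(np.zeros(10), grid)
        path = propagate(process("linear", c=1.0), grid, noise, 0.0)
        np.testing.assert_allclose(path.positions, 0.1 * np.arange(11), atol=1e-14)
        assert path.positions[-1] == pytest.approx(1.0)

    def test_grid_mismatch_rejected(self, grid):
        other = TimeGrid(dt=0.02, n_steps=50)
        noise = NoiseHistory(np.zeros(50), other)
        with pytest.raises(ValueError):
            propagate(process("zero"), grid, noise, 0.0)

    def test_unstable_step_fails_loudly(self):
        grid = TimeGrid(dt=1.0, n_steps=100)
        noise = NoiseHistory(np.full(100, 1.0), grid)
        with pytest.raises(FloatingPointError, match="step"):
            propagate(process("harmonic", A=1e8), grid, noise, 1.0)

    def test_ensemble_matches_single_path_route(self, grid):
        noises = sample_noise(grid, 4, 3)
        proc = process("harmonic", A=1.0)
        ens = propagate_ensemble(proc, grid, noises, 0.2)
        for n, p in zip(noises, ens):
            np.testing.assert_array_equal(
                p.positions, propagate(proc, grid, n, 0.2).positions
            )
        fast = sample_paths(proc, grid, 4, 3, x0=0.2)
        for p, q in zip(ens, fast):
            np.testing.assert_array_equal(p.positions, q.positions)


class TestRecoverNoise:
    def test_straight_path_under_zero_force(self):
        grid = TimeGrid(dt=0.01, n_steps=100)
        path = Path(0.01 * np.arange(101), grid)
        xi = recover_noise(process("zero", eps=0.5), path)
        np.testing.assert_allclose(xi.values, np.full(100, 0.1), atol=1e-12)

    def test_constant_path_gives_zero_noise(self, grid):
        path = Path(np.full(grid.n_steps + 1, 1.3), grid)
        xi = recover_noise(process("zero"), path)
        np.testing.assert_array_equal(xi.values, np.zeros(grid.n_steps))

    def test_round_trip_bijection(self, grid, any_process, rng):
        noise = NoiseHistory(rng.standard_normal(grid.n_steps), grid)
        path = propagate(any_process, grid, noise, 0.1)
        back = recover_noise(any_process, path)
        np.testing.assert_allclose(back.values, noise.values, atol=1e-12)
        again = propagate(any_process, grid, back, 0.1)
        np.testing.assert_allclose(again.positions, path.positions, atol=1e-12)


class TestMapPath:
    def test_identity_map(self, grid, any_process, rng):
        path = sample_paths(any_process, grid, 1, 5)[0]
        mapped = map_path(path, any_process)
        np.testing.assert_allclose(mapped.positions, path.positions, atol=1e-12)

    def test_constant_drift_shift_is_exact(self, mc_grid):
        z = sample_paths(process("zero"), mc_grid, 1, 9)[0]
        x = map_path(z, process("linear", c=1.0))
        np.testing.assert_allclose(
            x.positions, z.positions + 1.0 * mc_grid.times(), atol=1e-10
        )

    def test_map_is_invertible(self, grid, rng):
        qa, qb = process("harmonic", A=2.0), process("linear", c=-0.5)
        z = sample_paths(qb, grid, 1, 13)[0]
        back = map_path(map_path(z, qa, source=qb), qb, source=qa)
        np.testing.assert_allclose(back.positions, z.positions, atol=1e-12)


class TestOUExactStep:
    def test_half_life(self):
        assert ou_exact_step(1.0, math.log(2.0), EPS, 1.0, 0.0) == pytest.approx(0.5)

    def test_small_step_limit_matches_euler(self):
        A, dt, xi, x = 1.0, 1e-6, 0.8, 0.5
        euler = x - A * x * dt + math.sqrt(2 * EPS * dt) * xi
        assert ou_exact_step(x, A, EPS, dt, xi) == pytest.approx(euler, abs=1e-8)

    def test_stationary_variance(self):
        rng = np.random.default_rng(17)
        x = np.zeros(20000)
        for _ in range(120):
            x = ou_exact_step(x, 1.0, EPS, 0.1, rng.standard_normal(x.size))
        se = (EPS / 1.0) * math.sqrt(2.0 / x.size)  # light autocorrelation left
        assert abs(x.var() - EPS / 1.0) < 5 * se

    def test_invalid_A(self):
        with pytest.raises(ValueError):
            ou_exact_step(1.0, 0.0, EPS, 0.1, 0.0)


class TestBridges:
    def test_brownian_bridge_endpoints_exact(self):
        grid = TimeGrid(dt=0.01, n_steps=100)
        for p in sample_brownian_bridge(grid, EPS, -0.3, 1.7, 20, 3):
            assert p.positions[0] == -0.3
            assert p.positions[-1] == 1.7

    def test_brownian_bridge_midpoint_variance(self):
        # Var at t = T/2 with x0 = xT = 0 is 2 eps t (1 - t/T) = 0.25
        grid = TimeGrid(dt=0.01, n_steps=100)
        pos = positions_matrix(sample_brownian_bridge(grid, EPS, 0.0, 0.0, 20000, 4))
        v = pos[:, 50].var(ddof=1)
        se = 0.25 * math.sqrt(2.0 / (pos.shape[0] - 1))
        assert abs(v - 0.25) < 3 * se
        assert pos[:, 0].var() == 0.0
        assert pos[:, -1].var() == 0.0

    def test_ou_bridge_endpoints_exact(self):
        grid = TimeGrid(dt=0.01, n_steps=100)
        for p in sample_ou_bridge(grid, EPS, 1.5, 0.2, -0.4, 20, 5):
            assert p.positions[0] == 0.2
            assert p.positions[-1] == -0.4

    def test_ou_bridge_marginal_variance_closed_form(self):
        # conditional-variance oracle from the joint Gaussian covariance:
        # Var(x_t | x_0 = x_T = 0) = 2 (eps/A) sinh(At) sinh(A(T-t)) / sinh(AT)
        A, T = 1.5, 1.0
        grid = TimeGrid(dt=0.01, n_steps=100)
        pos = positions_matrix(sample_ou_bridge(grid, EPS, A, 0.0, 0.0, 20000, 6))
        t = grid.times()
        ref = 2 * (EPS / A) * np.sinh(A * t) * np.sinh(A * (T - t)) / np.sinh(A * T)
        mc = pos.var(axis=0, ddof=1)
        se = ref * math.sqrt(2.0 / (pos.shape[0] - 1))
        idx = [10, 25, 50, 75, 90]
        assert np.all(np.abs(mc[idx] - ref[idx]) < 4 * se[idx])

    def test_ou_bridge_continuity_in_A(self):
        # A -> 0 recovers the Brownian-bridge variance profile
        grid = TimeGrid(dt=0.01, n_steps=100)
        pos = positions_matrix(sample_ou_bridge(grid, EPS, 1e-8, 0.0, 0.0, 20000, 7))
        t = grid.times()
        ref = 2 * EPS * t * (1 - t / grid.duration)
        mc = pos.var(axis=0, ddof=1)
        idx = [10, 25, 50, 75, 90]
        se = ref[idx] * math.sqrt(2.0 / (pos.shape[0] - 1))
        assert np.all(np.abs(mc[idx] - ref[idx]) < 4 * se)


def test_free_brownian_terminal_variance():
    """Sample variance of x_T matches 2 eps T for free diffusion."""
    grid = TimeGrid(dt=1e-3, n_steps=1000)
    ens = sample_paths(process("zero"), grid, 10000, 23)
    xT = np.array([p.positions[-1] for p in ens])
    ref = 2 * EPS * grid.duration
    se = ref * math.sqrt(2.0 / (len(xT) - 1))
    assert abs(xT.var(ddof=1) - ref) < 3 * se


def test_euler_converges_to_exact_ou_kernel():
    """Terminal second moment of Euler OU approaches the exact kernel as O(dt)."""
    A, n_mc = 1.0, 40000
    ref = (EPS / A) * (1 - math.exp(-2 * A))
    errs = []
    for nt in (10, 40, 160):
        grid = TimeGrid(dt=1.0 / nt, n_steps=nt)
        ens = sample_paths(process("harmonic", A=A), grid, n_mc, 29)
        m2 = np.mean([p.positions[-1] ** 2 for p in ens])
        errs.append(abs(m2 - ref))
    # quartering dt (twice) must cut the bias well below half; MC noise at
    # this ensemble size is an order of magnitude under the coarsest bias
    assert errs[1] < errs[0]
    assert errs[2] < errs[0] / 2
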