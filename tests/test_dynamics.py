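"""Field integration, learning rule, training loop, and equilibrium solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from nfsom.grid_kernels import SpatialGrid, KernelSpec, kernel_on_grid
from nfsom.dynamics import (
    ModelParams,
    EquilibriumError,
    equilibrium_field,
    field_step,
    input_drive,
    lyapunov_value,
    rect,
    run_epoch,
    train,
    weights_step,
)

STABLE = KernelSpec(0.90, 0.1, 0.86, 1.0)
BALANCED = KernelSpec(0.5, 0.3, 0.5, 0.3)     # w_l identically zero


class TestInputDrive:
    @pytest.mark.parametrize("w, p, expected", [
        ((0.3, 0.7), (0.3, 0.7), 1.0),
        ((0.0, 0.0), (1.0, 1.0), 0.0),
        ((1.0, 0.0), (0.0, 0.0), 0.5),
    ])
    def test_examples(self, w, p, expected):
        w_field = np.broadcast_to(np.asarray(w), (4, 4, 2))
        assert np.allclose(input_drive(w_field, np.asarray(p)), expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            input_drive(np.zeros((4, 4, 2)), np.zeros(3))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        I = input_drive(rng.random((5, 5, 3)), rng.random(3))
        assert np.all((I >= 0.0) & (I <= 1.0))


class TestFieldStep:
    def test_euler_arithmetic_with_zero_kernel(self):
        grid = SpatialGrid(0.0, 1.0, 6, 2)
        table = kernel_on_grid(BALANCED, grid)
        params = ModelParams(tau=1.0, dt=0.015, t_epoch=1.0)
        u = field_step(np.zeros(grid.shape), np.ones(grid.shape), table, params, grid)
        assert np.allclose(u, 0.015)

    def test_equilibrium_is_fixed_point(self, small_grid):
        table = kernel_on_grid(STABLE, small_grid)
        u_star = equilibrium_field(table, small_grid, tol=1e-13)
        params = ModelParams(dt=0.015, t_epoch=1.0)
        stepped = field_step(u_star, np.ones(small_grid.shape), table, params, small_grid)
        assert np.allclose(stepped, u_star, atol=1e-11)

    def test_first_order_convergence_in_dt(self, small_grid):
        # integrate u' = (-u + conv(rect u) + 1)/tau to T with dt and dt/2;
        # the error against a dt/20 reference should halve.
        table = kernel_on_grid(STABLE, small_grid)
        rng = np.random.default_rng(5)
        u0 = rng.random(small_grid.shape)
        T = 0.6

        def integrate_to(dt):
            params = ModelParams(dt=dt, t_epoch=1.0)
            u = u0.copy()
            for _ in range(int(round(T / dt))):
                u = field_step(u, np.ones(small_grid.shape), table, params, small_grid)
            return u

        ref = integrate_to(0.003)
        err1 = np.abs(integrate_to(0.06) - ref).max()
        err2 = np.abs(integrate_to(0.03) - ref).max()
        assert err2 / err1 == pytest.approx(0.5, abs=0.15)


class TestWeightsStep:
    def test_converged_codebook_is_stationary(self, small_grid):
        exc = kernel_on_grid(STABLE, small_grid, "excitatory")
        params = ModelParams(dt=0.015, t_epoch=1.0, gamma=0.1)
        p = np.array([0.4, 0.6])
        w = np.broadcast_to(p, small_grid.shape + (2,)).copy()
        out = weights_step(w, np.ones(small_grid.shape), p, exc, params, small_grid)
        assert np.array_equal(out, w)

    def test_rectification_gates_learning(self, small_grid):
        exc = kernel_on_grid(STABLE, small_grid, "excitatory")
        params = ModelParams(dt=0.015, t_epoch=1.0, gamma=0.1)
        rng = np.random.default_rng(0)
        w = rng.random(small_grid.shape + (2,))
        out = weights_step(w, -np.ones(small_grid.shape), np.array([0.5, 0.5]),
                           exc, params, small_grid)
        assert np.array_equal(out, w)

    def test_step_contracts_distance_to_stimulus(self, small_grid):
        exc = kernel_on_grid(STABLE, small_grid, "excitatory")
        params = ModelParams(dt=0.015, t_epoch=1.0, gamma=0.5)
        rng = np.random.default_rng(1)
        w = rng.random(small_grid.shape + (2,))
        u = rng.random(small_grid.shape)          # positive somewhere
        p = np.array([0.2, 0.9])
        out = weights_step(w, u, p, exc, params, small_grid)
        before = np.abs(w - p).sum(-1)
        after = np.abs(out - p).sum(-1)
        from nfsom.grid_kernels import lateral_convolve
        E = lateral_convolve(rect(u), exc, small_grid)
        assert np.all(after[E > 0] < before[E > 0])


class TestRunEpoch:
    def test_step_count_from_horizon(self):
        assert ModelParams(dt=0.015, t_epoch=25.0).steps_per_epoch == 1666

    def test_zero_learning_rate_freezes_codebook(self, small_grid):
        params = ModelParams(gamma=0.0, dt=0.015, t_epoch=0.5)
        rng = np.random.default_rng(2)
        w0 = rng.random(small_grid.shape + (2,))
        w1, _ = run_epoch(np.zeros(small_grid.shape), w0, np.array([0.5, 0.5]),
                          STABLE, params, small_grid)
        assert np.array_equal(w0, w1)

    def test_single_step_matches_field_and_weight_steps(self, small_grid):
        params = ModelParams(dt=0.015, t_epoch=0.015, gamma=0.3, conv_norm="integral")
        lat = kernel_on_grid(STABLE, small_grid, "lateral")
        exc = kernel_on_grid(STABLE, small_grid, "excitatory")
        rng = np.random.default_rng(3)
        u0 = rng.random(small_grid.shape)
        w0 = rng.random(small_grid.shape + (2,))
        p = np.array([0.3, 0.8])
        w1, diag = run_epoch(u0, w0, p, STABLE, params, small_grid)
        I = input_drive(w0, p)
        u_expected = field_step(u0, I, lat, params, small_grid)
        w_expected = weights_step(w0, u0, p, exc, params, small_grid)
        assert np.allclose(diag["field_final"], u_expected, atol=1e-12)
        assert np.allclose(w1, w_expected, atol=1e-12)

    def test_stable_epoch_stays_bounded(self, small_grid):
        params = ModelParams(dt=0.015, t_epoch=25.0)
        rng = np.random.default_rng(4)
        w0 = rng.uniform(0, 0.01, small_grid.shape + (2,))
        w1, diag = run_epoch(np.zeros(small_grid.shape), w0, np.array([0.6, 0.2]),
                             STABLE, params, small_grid)
        assert np.all(np.isfinite(diag["field_final"]))
        assert diag["field_max"] < 10.0


class TestTrain:
    def test_zero_epochs_returns_initialization(self, small_grid):
        params = ModelParams(epochs=0, t_epoch=1.0)
        result = train(params, STABLE, small_grid, seed=11)
        expected = np.random.default_rng(11).uniform(0, 0.01, small_grid.shape + (2,))
        assert np.array_equal(result.codebook, expected)
        assert result.trace.empty

    def test_same_seed_is_bitwise_reproducible(self, small_grid):
        params = ModelParams(epochs=5, t_epoch=1.0, gamma=0.05)
        r1 = train(params, STABLE, small_grid, seed=77)
        r2 = train(params, STABLE, small_grid, seed=77)
        assert np.array_equal(r1.codebook, r2.codebook)
        assert r1.trace.equals(r2.trace)
        assert np.array_equal(r1.samples, r2.samples)

    def test_codebook_stays_in_unit_cube_along_trajectory(self, small_grid):
        params = ModelParams(epochs=40, t_epoch=2.0, gamma=0.2)
        seen = []
        train(params, STABLE, small_grid, seed=5,
              callback=lambda e, w: seen.append((w.min(), w.max())))
        lo = min(s[0] for s in seen)
        hi = max(s[1] for s in seen)
        assert 0.0 <= lo and hi <= 1.0

    def test_distortion_declines_on_short_stable_run(self, small_grid):
        params = ModelParams(epochs=150, t_epoch=5.0, gamma=0.05)
        result = train(params, STABLE, small_grid, seed=10, log_stride=5)
        d = result.trace["distortion"]
        assert d.iloc[-5:].mean() < d.iloc[:5].mean()


class TestEquilibriumField:
    def test_zero_kernel_gives_unit_field(self, small_grid):
        table = np.zeros((15, 15))
        u = equilibrium_field(table, small_grid)
        assert np.array_equal(u, np.ones(small_grid.shape))

    def test_balanced_kernel_gives_unit_field(self, small_grid):
        table = kernel_on_grid(BALANCED, small_grid)
        u = equilibrium_field(table, small_grid)
        assert np.allclose(u, 1.0, atol=1e-12)

    def test_matches_root_finder_oracle(self, desk_grid):
        from nfsom.grid_kernels import lateral_convolve
        table = kernel_on_grid(STABLE, desk_grid)
        u = equilibrium_field(table, desk_grid, tol=1e-12)
        residual = np.abs(u - (1 + lateral_convolve(rect(u), table, desk_grid))).max()
        assert residual <= 1e-10

        def F(v):
            v = v.reshape(desk_grid.shape)
            return (v - 1 - lateral_convolve(rect(v), table, desk_grid)).ravel()

        oracle = optimize.root(F, np.ones(desk_grid.k), method="krylov",
                               options={"fatol": 1e-12}).x.reshape(desk_grid.shape)
        assert np.allclose(u, oracle, atol=1e-8)

    def test_nonconvergence_raises_with_residual(self, small_grid):
        table = kernel_on_grid(KernelSpec(30.0, 0.3, 1.0, 1.0), small_grid)
        with pytest.raises(EquilibriumError) as excinfo:
            equilibrium_field(table, small_grid, max_iter=200)
        assert excinfo.value.residual > 0


class TestLyapunov:
    def test_zero_deviation_gives_zero(self, small_grid):
        assert lyapunov_value(np.zeros(small_grid.shape),
                              np.zeros(small_grid.shape + (2,)),
                              rho=1.0, tau=1.0, gamma=0.01, grid=small_grid) == 0.0

    def test_unit_field_deviation_on_unit_square(self):
        grid = SpatialGrid(0.0, 1.0, 16, 2)
        v = lyapunov_value(np.ones(grid.shape), np.zeros(grid.shape + (2,)),
                           rho=1.0, tau=2.0, gamma=0.01, grid=grid)
        assert v == pytest.approx(1.0, rel=1e-12)

    def test_field_converges_to_fixed_point_with_frozen_weights(self, small_grid):
        # gamma = 0, constant input: u must approach the unique fixed point
        # and the L2 distance must decay with a negative fitted log-slope.
        table = kernel_on_grid(STABLE, small_grid)
        u_star = equilibrium_field(table, small_grid, tol=1e-13)
        params = ModelParams(dt=0.015, t_epoch=1.0)
        u = np.zeros(small_grid.shape)
        norms = []
        for _ in range(800):
            u = field_step(u, np.ones(small_grid.shape), table, params, small_grid)
            norms.append(np.sqrt(((u - u_star) ** 2).sum() * small_grid.cell_measure))
        norms = np.array(norms)
        assert norms[-1] < 1e-6 * norms[0]
        slope = np.polyfit(np.arange(300), np.log(norms[:300]), 1)[0]
        assert slope < 0
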