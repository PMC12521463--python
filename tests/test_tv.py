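"""Tests of the 1D TV-l2 denoiser and its ADMM solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tvbold as tb
from tvbold.data import InvalidInputError
from tvbold.tv import _admm_relative, forward_diff_adjoint

from oracles import brute_force_tv, dense_forward_diff_matrix, exact_tv_l2

finite_series = st.lists(
    st.floats(-1e4, 1e4, allow_nan=False, allow_infinity=False),
    min_size=2, max_size=40,
).map(np.asarray)


class TestForwardDiff:
    @pytest.mark.parametrize(
        "x, expected",
        [([5, 5, 5, 5], [0, 0, 0, 0]), ([1, 2, 4, 4], [1, 2, 0, 0])],
    )
    def test_definition(self, x, expected):
        np.testing.assert_array_equal(tb.forward_diff(x), expected)

    def test_matches_dense_matrix(self, rng):
        x = rng.normal(size=17)
        D = dense_forward_diff_matrix(17)
        np.testing.assert_allclose(tb.forward_diff(x), D @ x, atol=1e-12)

    def test_adjoint_matches_dense_transpose(self, rng):
        x, y = rng.normal(size=(2, 23))
        D = dense_forward_diff_matrix(23)
        np.testing.assert_allclose(forward_diff_adjoint(y), D.T @ y, atol=1e-12)
        # adjoint identity <Dx, y> = <x, D^T y>
        assert tb.forward_diff(x) @ y == pytest.approx(x @ forward_diff_adjoint(y))

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            tb.forward_diff([1.0])


class TestTotalVariation:
    def test_monotone_series_equals_endpoint_difference(self):
        # for a monotone path the TV collapses to |end - start|
        x = np.linspace(3.0, 11.0, 25) ** 1.5
        assert tb.total_variation(x) == pytest.approx(abs(x[-1] - x[0]))

    def test_unit_jump_count(self):
        assert tb.total_variation([0, 1, 0, 1, 0]) == 4

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=33)
        assert tb.total_variation(x) == pytest.approx(brute_force_tv(x))

    @given(finite_series)
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_and_zero_iff_constant(self, x):
        tv = tb.total_variation(x)
        assert tv >= 0
        assert (tv == 0) == bool(np.all(x == x[0]))


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "d, lam_i, beta, expected",
        [
            (0.7, 0.7, 1.0, 0.0),        # argument exactly zero
            (1.5, 1.0, 2.0, 0.5),        # 1.5-0.5=1.0, minus 1/2 -> 0.5
            (2.0, 0.0, 1.0, 1.0),        # max(2-1,0)*sgn(2)
            (-2.0, 0.0, 1.0, -1.0),
        ],
    )
    def test_values(self, d, lam_i, beta, expected):
        assert tb.soft_threshold_update(d, lam_i, beta) == pytest.approx(expected)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0.1, 10))
    @settings(max_examples=100, deadline=None)
    def test_dead_zone_and_shrinkage(self, d, lam_i, beta):
        out = tb.soft_threshold_update(d, lam_i, beta)
        v = d - lam_i / beta
        if abs(v) <= 1.0 / beta:
            assert out == 0.0
        else:
            assert abs(out) == pytest.approx(abs(v) - 1.0 / beta)
            assert np.sign(out) == np.sign(v)

    def test_invalid_beta(self):
        with pytest.raises(InvalidInputError):
            tb.soft_threshold_update(1.0, 0.0, 0.0)


class TestAdmmDenoise1D:
    def test_constant_input_is_fixed_point(self):
        b = np.full(50, 123.4)
        u = tb.admm_denoise_1d(b)
        np.testing.assert_allclose(u, b, atol=1e-8 * 123.4)

    def test_spike_removed_near_exact_minimiser(self):
        b = np.full(64, 100.0)
        b[30] += 50.0
        p = tb.DenoiseParams(mu=2.0**-4)
        u = tb.admm_denoise_1d(b, p)
        ustar = exact_tv_l2(b, p.mu)
        G = tb.tv_l2_objective(u, b, p.mu)
        Gstar = tb.tv_l2_objective(ustar, b, p.mu)
        assert G <= Gstar * 1.01
        # the 50-unit spike is shrunk to the soft-threshold residual
        assert u[30] - 100.0 < 50.0 * 0.5

    def test_objective_within_1pct_of_oracle(self, rng):
        from conftest import bold_like_series

        B = bold_like_series(rng, 50, 32)
        p = tb.DenoiseParams()
        hits = 0
        for b in B:
            u = tb.admm_denoise_1d(b, p)
            gap = tb.tv_l2_objective(u, b, p.mu) / tb.tv_l2_objective(
                exact_tv_l2(b, p.mu), b, p.mu) - 1.0
            hits += gap <= 0.01
        assert hits >= 48  # >= 95% of 50

    def test_tv_and_objective_never_increase(self, rng):
        from conftest import bold_like_series

        B = bold_like_series(rng, 200, 30)
        U = tb.denoise_batch(B)
        p = tb.DenoiseParams()
        for b, u in zip(B, U):
            assert tb.total_variation(u) <= tb.total_variation(b) + 1e-9
            assert tb.tv_l2_objective(u, b, p.mu) <= tb.tv_l2_objective(b, b, p.mu)

    def test_objective_monotone_over_outer_iterations(self, rng):
        from conftest import bold_like_series

        b = bold_like_series(rng, 1, 48)[0]
        p = tb.DenoiseParams()
        vals = []
        for k in (1, 5, 25, 100, 400):
            u = tb.admm_denoise_1d(b, tb.DenoiseParams(outer_iters=k))
            vals.append(tb.tv_l2_objective(u, b, p.mu))
        assert all(v2 <= v1 + 1e-6 * abs(v1) for v1, v2 in zip(vals, vals[1:]))

    def test_local_mean_preserved_on_piecewise_constant(self, rng):
        # two 60-frame plateaus + zero-mean noise: segment means survive
        sd = 200.0
        levels = [10000.0, 12000.0]
        b = np.concatenate([np.full(60, levels[0]), np.full(60, levels[1])])
        b = b + rng.normal(0, sd, b.size)
        u = tb.admm_denoise_1d(b)
        se = sd / np.sqrt(60)
        assert abs(u[:60].mean() - levels[0]) < 2 * se + abs(b[:60].mean() - levels[0])
        assert abs(u[60:].mean() - levels[1]) < 2 * se + abs(b[60:].mean() - levels[1])

    def test_scale_relation_of_objective(self, rng):
        # G_c(c*u) = c*||Du||_1 + c^2*(mu/2)||u-b||^2: TV is 1-homogeneous,
        # the fidelity term 2-homogeneous, so denoising is not scale covariant
        b = rng.normal(1000, 100, 40)
        u = tb.admm_denoise_1d(b)
        mu = tb.DenoiseParams().mu
        c = 3.7
        lhs = tb.tv_l2_objective(c * u, c * b, mu)
        rhs = c * tb.total_variation(u) + c**2 * 0.5 * mu * np.sum((u - b) ** 2)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_relative_error_stop_converges_to_same_solution(self, rng):
        b = rng.normal(10000, 200, 40)
        p = tb.DenoiseParams(use_relative_error_stop=True, sigma=0.25)
        u_rel = tb.admm_denoise_1d(b, p)
        u_fix = tb.admm_denoise_1d(b, tb.DenoiseParams())
        mu = p.mu
        assert tb.tv_l2_objective(u_rel, b, mu) <= 1.05 * tb.tv_l2_objective(u_fix, b, mu)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(InvalidInputError):
            tb.admm_denoise_1d([1.0, np.nan, 2.0])


class TestDenoiseMultiEcho:
    def test_noise_free_phantom_unchanged_in_time_constant_voxels(self, task_design):
        spec = tb.PhantomSpec(dims=(3, 3, 1), design=None, frames=40,
                              noise_sd=0.0, spike_prob=0.0, seed=5)
        Y, _ = tb.generate_phantom(spec)
        out = tb.denoise_multi_echo(Y)
        np.testing.assert_allclose(out.data, Y.data, rtol=0, atol=1e-8 * Y.data.max())

    def test_matches_manual_voxel_loop(self, small_task_phantom):
        _, Y, _ = small_task_phantom
        sub = tb.MultiEchoSeries(data=Y.data[:2, :2, :1], te=Y.te, tr_s=Y.tr_s)
        p = tb.DenoiseParams(outer_iters=20)
        out = tb.denoise_multi_echo(sub, p)
        for r in range(2):
            for c in range(2):
                for e in range(3):
                    manual = tb.admm_denoise_1d(sub.data[r, c, 0, e], p)
                    np.testing.assert_array_equal(out.data[r, c, 0, e], manual)

    def test_spiked_voxels_lose_tv_and_mask_respected(self, small_task_phantom):
        _, Y, _ = small_task_phantom
        mask = np.zeros(Y.spatial_shape, dtype=bool)
        mask[:3] = True
        out = tb.denoise_multi_echo(Y, mask=mask)
        e2_in, e2_out = Y.echo(1), out.echo(1)
        tv_in = np.abs(np.diff(e2_in, axis=-1)).sum(axis=-1)
        tv_out = np.abs(np.diff(e2_out, axis=-1)).sum(axis=-1)
        assert np.all(tv_out[mask] < tv_in[mask])
        np.testing.assert_array_equal(e2_out[~mask], e2_in[~mask])

    def test_dimension_mismatch_rejected(self, small_task_phantom):
        _, Y, _ = small_task_phantom
        with pytest.raises(InvalidInputError):
            tb.denoise_multi_echo(Y, mask=np.ones((2, 2, 2), dtype=bool))
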