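"""The ICON iteration, its building blocks, and the WBP baseline."""

import numpy as np
import pytest

from iconet import (
    PhantomSpec,
    ReconConfig,
    TiltScheme,
    build_sampling_plan,
    gray_value_adjust,
    icon_reconstruct_slice,
    make_phantom_slice,
    make_tilt_scheme,
    ncc,
    positivity_threshold,
    reconstruct_volume,
    simulate_sinogram,
    wbp_reconstruct_slice,
)
from iconet.nufft import NufftOperator, _ndft_matrix
from iconet.reconstruction import fidelity_step, sinogram_to_fourier


class TestGrayValueAdjust:
    def test_dominant_value_subtracted(self, rng):
        stack = np.full((3, 10, 10), 7.0)
        noisy = rng.normal(size=30).reshape(3, 10)  # 10% of pixels
        stack[:, 0, :] = 20.0 + noisy
        adjusted, mode = gray_value_adjust(stack)
        assert mode == pytest.approx(7.0, abs=0.1)
        assert np.abs(adjusted[:, 1:, :]).max() < 0.1

    def test_all_zero_stack_unchanged(self):
        stack = np.zeros((2, 4, 4))
        adjusted, mode = gray_value_adjust(stack)
        assert mode == 0.0
        assert np.all(adjusted == 0)

    def test_constant_stack_becomes_zero(self):
        adjusted, mode = gray_value_adjust(np.full((2, 4, 4), 3.5))
        assert mode == 3.5
        assert np.all(adjusted == 0)

    def test_recovers_known_background(self):
        # synthetic sinogram with constant background and sparse foreground
        phantom = make_phantom_slice(PhantomSpec(N=32, n_blobs=3, seed=2))
        scheme = make_tilt_scheme(-60, 60, 10)
        sino = simulate_sinogram(phantom, scheme, background=5.0)
        _, mode = gray_value_adjust(sino, n_bins=256)
        bin_width = (sino.max() - sino.min()) / 256
        assert abs(mode - 5.0) <= bin_width


class TestSinogramToFourier:
    def test_constant_row_energy_at_dc(self):
        N = 8
        plan = build_sampling_plan(TiltScheme([0.0]), N)
        f = sinogram_to_fourier(np.full((1, N), 3.0), plan)
        dc = plan.freq_index == 0
        assert f[dc] == pytest.approx(3.0 * N)
        assert np.abs(f[~dc]).max() < 1e-12

    def test_matches_direct_centered_dft(self, rng):
        N = 16
        plan = build_sampling_plan(TiltScheme([0.0]), N)
        row = rng.normal(size=N)
        f = sinogram_to_fourier(row[None], plan)
        u = np.arange(-N // 2, N // 2)
        s = plan.freq_index
        direct = np.array([np.sum(row * np.exp(-2j * np.pi * si * u / N)) for si in s])
        np.testing.assert_allclose(f, direct, atol=1e-10 * np.abs(direct).max())

    def test_hermitian_symmetry_for_real_rows(self, rng):
        N = 16
        plan = build_sampling_plan(TiltScheme([-10.0, 20.0]), N)
        f = sinogram_to_fourier(rng.normal(size=(2, N)), plan)
        for t in range(2):
            for s in range(1, N // 2):
                fp = f[(plan.tilt_index == t) & (plan.freq_index == s)][0]
                fm = f[(plan.tilt_index == t) & (plan.freq_index == -s)][0]
                assert fp == pytest.approx(np.conj(fm))

    def test_shape_mismatch_rejected(self):
        plan = build_sampling_plan(TiltScheme([0.0]), 8)
        with pytest.raises(ValueError):
            sinogram_to_fourier(np.zeros((2, 8)), plan)


class TestPositivityThreshold:
    def test_pointwise_rule(self):
        y = np.array([[-3.0, 5.0], [0.0, -0.1]])
        np.testing.assert_array_equal(
            positivity_threshold(y), [[0.0, 5.0], [0.0, 0.0]]
        )

    def test_all_negative_goes_to_zero(self):
        assert np.all(positivity_threshold(-np.ones((4, 4))) == 0)

    def test_idempotent(self, rng):
        y = rng.normal(size=(16, 16))
        once = positivity_threshold(y)
        np.testing.assert_array_equal(positivity_threshold(once), once)


class TestFidelityStep:
    @staticmethod
    def setup_case(N=8, seed=3):
        scheme = make_tilt_scheme(-60, 60, 20)
        plan = build_sampling_plan(scheme, N)
        phantom = make_phantom_slice(PhantomSpec(N=N, n_blobs=2, seed=seed))
        sino = simulate_sinogram(phantom, scheme)
        f = sinogram_to_fourier(sino, plan)
        op = NufftOperator(plan, backend="direct")
        return plan, phantom, f, op

    def test_consistent_data_is_fixed_point(self):
        # f constructed as A x itself: exactly consistent, r = 0
        plan, phantom, _, op = self.setup_case()
        f = op.forward(phantom)
        y, alpha, info = fidelity_step(phantom, f, op, plan.weights)
        assert info["residual_norm"] <= 1e-10 * np.abs(f).max()
        np.testing.assert_array_equal(y, phantom)

    def test_matches_dense_matrix_oracle(self):
        # brute-force the whole step with an explicit AᴴWA matrix
        plan, phantom, f, op = self.setup_case()
        N = plan.N
        x0 = np.zeros((N, N))
        y, alpha, info = fidelity_step(x0, f, op, plan.weights)
        E = _ndft_matrix(plan.points, N)
        B = (E.conj().T * plan.weights) @ E
        rhs = (E.conj().T * plan.weights) @ f
        r = (B @ x0.ravel() - rhs).real
        alpha_oracle = (r @ r) / (r @ (B @ r).real)
        y_oracle = (x0.ravel() - alpha_oracle * r).reshape(N, N)
        assert alpha == pytest.approx(alpha_oracle, rel=1e-8)
        np.testing.assert_allclose(y, y_oracle, atol=1e-8 * np.abs(y_oracle).max())
        assert info["residual_norm"] == pytest.approx(np.linalg.norm(r), rel=1e-8)

    def test_exact_line_search_decreases_fidelity(self, rng):
        plan, phantom, f, op = self.setup_case()
        x = positivity_threshold(rng.normal(size=(plan.N, plan.N)))
        _, alpha, info = fidelity_step(x, f, op, plan.weights)
        assert alpha > 0
        assert info["q_after"] <= info["q_before"]


class TestIconReconstruct:
    def test_zero_sinogram_converges_to_zero_immediately(self):
        scheme = make_tilt_scheme(-60, 60, 10)
        rec, trace = icon_reconstruct_slice(np.zeros((scheme.n_tilts, 16)), scheme)
        assert np.all(rec == 0)
        assert trace.converged
        assert len(trace) == 1

    def test_full_coverage_recovers_phantom(self):
        # 0..179 degrees, noiseless: near-perfect parameter recovery
        phantom = make_phantom_slice(PhantomSpec(N=32, n_blobs=5, seed=1))
        scheme = make_tilt_scheme(0, 179, 1)
        sino = simulate_sinogram(phantom, scheme)
        rec, _ = icon_reconstruct_slice(sino, scheme, ReconConfig(n_iter=200))
        assert ncc(rec, phantom) >= 0.95

    def test_iterates_stay_non_negative_and_q_decreases_within_steps(
        self, small_case_32
    ):
        phantom, sino, scheme = small_case_32
        rec, trace = icon_reconstruct_slice(sino, scheme, ReconConfig(n_iter=50))
        assert rec.min() >= 0
        qb = np.array(trace.q_before)
        qa = np.array(trace.q_after)
        assert np.all(qa <= qb + 1e-9 * np.abs(qb))

    def test_trace_has_one_entry_per_iteration(self, small_case_32):
        _, sino, scheme = small_case_32
        _, trace = icon_reconstruct_slice(sino, scheme, ReconConfig(n_iter=17))
        assert len(trace) == 17
        assert trace.stop_reason == "n_iter"
        df = trace.to_dataframe()
        assert list(df.columns[:3]) == ["iteration", "residual_norm", "alpha"]

    def test_backend_equivalence_scaled(self, small_case_32):
        # fast gridding vs direct-summation oracle backend, same input
        phantom, sino, scheme = small_case_32
        fast, _ = icon_reconstruct_slice(sino, scheme, ReconConfig(n_iter=60))
        oracle, _ = icon_reconstruct_slice(
            sino, scheme, ReconConfig(n_iter=60, backend="direct")
        )
        assert ncc(fast, oracle) >= 0.999

    def test_wbp_init_mode_runs(self, small_case_32):
        _, sino, scheme = small_case_32
        rec, _ = icon_reconstruct_slice(
            sino, scheme, ReconConfig(n_iter=10, init_mode="wbp")
        )
        assert rec.min() >= 0

    def test_stop_epsilon_halts_early(self, small_case_32):
        _, sino, scheme = small_case_32
        _, trace_free = icon_reconstruct_slice(sino, scheme, ReconConfig(n_iter=30))
        eps = trace_free.residual_norm[10]
        _, trace = icon_reconstruct_slice(
            sino, scheme, ReconConfig(n_iter=30, stop_epsilon=eps)
        )
        assert len(trace) < 30
        assert trace.stop_reason == "stop_epsilon"


class TestWbpBaseline:
    def test_zero_sinogram_zero_slice(self):
        scheme = make_tilt_scheme(-60, 60, 10)
        rec = wbp_reconstruct_slice(np.zeros((scheme.n_tilts, 16)), scheme)
        assert np.all(rec == 0)

    def test_point_phantom_peaks_at_centre(self):
        N = 32
        phantom = np.zeros((N, N))
        phantom[N // 2, N // 2] = 1.0
        scheme = make_tilt_scheme(-60, 60, 4)  # T=31 tilts
        sino = simulate_sinogram(phantom, scheme)
        rec = wbp_reconstruct_slice(sino, scheme)
        assert np.unravel_index(np.argmax(rec), rec.shape) == (N // 2, N // 2)

    def test_matches_dense_adjoint_oracle(self):
        N = 8
        scheme = make_tilt_scheme(-60, 60, 30)
        phantom = make_phantom_slice(PhantomSpec(N=N, n_blobs=2, seed=6))
        sino = simulate_sinogram(phantom, scheme)
        rec = wbp_reconstruct_slice(sino, scheme, ReconConfig(backend="direct"))
        plan = build_sampling_plan(scheme, N)
        f = sinogram_to_fourier(sino, plan)
        E = _ndft_matrix(plan.points, N)
        oracle = ((E.conj().T * plan.weights) @ f).real.reshape(N, N)
        np.testing.assert_allclose(rec, oracle, atol=1e-8 * np.abs(oracle).max())


class TestReconstructVolume:
    @staticmethod
    def make_stack(rows=3, N=16, seed=0):
        scheme = make_tilt_scheme(-60, 60, 15)
        stack = np.zeros((scheme.n_tilts, rows, N))
        phantoms = []
        for r in range(rows):
            p = make_phantom_slice(PhantomSpec(N=N, n_blobs=2, seed=seed + r))
            phantoms.append(p)
            stack[:, r, :] = simulate_sinogram(p, scheme)
        return stack, scheme, phantoms

    def test_equals_stack_of_independent_slices(self):
        stack, scheme, _ = self.make_stack()
        cfg = ReconConfig(n_iter=10)
        volume, _ = reconstruct_volume(stack, scheme, cfg)
        adjusted, _ = gray_value_adjust(stack)
        for r in range(3):
            expected, _ = icon_reconstruct_slice(adjusted[:, r, :], scheme, cfg)
            np.testing.assert_array_equal(volume[r], expected)

    def test_processing_order_irrelevant(self):
        stack, scheme, _ = self.make_stack()
        cfg = ReconConfig(n_iter=5)
        v1, _ = reconstruct_volume(stack, scheme, cfg, rows=[0, 1, 2])
        v2, _ = reconstruct_volume(stack, scheme, cfg, rows=[2, 0, 1])
        np.testing.assert_array_equal(v1, v2)

    def test_zero_rows_stay_zero(self):
        scheme = make_tilt_scheme(-60, 60, 15)
        N = 16
        stack = np.zeros((scheme.n_tilts, 3, N))
        p = make_phantom_slice(PhantomSpec(N=N, n_blobs=2, seed=9))
        stack[:, 1, :] = simulate_sinogram(p, scheme)
        volume, _ = reconstruct_volume(stack, scheme, ReconConfig(n_iter=5))
        assert np.all(volume[0] == 0)
        assert np.all(volume[2] == 0)
        assert volume[1].max() > 0

    def test_depth_mismatch_rejected(self):
        stack, scheme, _ = self.make_stack()
        with pytest.raises(ValueError):
            reconstruct_volume(stack[:-1], scheme, ReconConfig(n_iter=2))
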