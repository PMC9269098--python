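"""DMD core: snapshot bookkeeping, optimal hard-threshold rank, eigenvalue
recovery against analytic and brute-force oracles, reconstruction and
prediction."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flipdmd as fd
from flipdmd.dmd import (
    gavish_donoho_omega,
    reconstruct_continuous,
    snapshots_to_stack,
    truncated_svd,
)
from flipdmd.stack import ImageStack


def decay_stack(factor=0.9, n=10, shape=(2, 2), dt=1.0):
    base = np.arange(1, shape[0] * shape[1] + 1, dtype=float).reshape(shape)
    return ImageStack(np.stack([base * factor**k for k in range(n)]), dt)


class TestSnapshots:
    def test_constructed_decay_columns(self):
        pair = fd.stack_to_snapshots(decay_stack(0.9, n=3))
        np.testing.assert_allclose(pair.X[:, 0], [1, 2, 3, 4])
        np.testing.assert_allclose(pair.X[:, 1], np.array([1, 2, 3, 4]) * 0.9)
        np.testing.assert_allclose(pair.X_prime[:, 1], np.array([1, 2, 3, 4]) * 0.81)

    def test_shift_property_and_shapes(self, basic_stack):
        stack, _ = basic_stack
        pair = fd.stack_to_snapshots(stack)
        assert pair.X.shape == (128 * 128, 299)
        np.testing.assert_array_equal(pair.X[:, 1:], pair.X_prime[:, :-1])

    @given(
        n_frames=st.integers(3, 8),
        h=st.integers(1, 6),
        w=st.integers(1, 6),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=30, deadline=None)
    def test_round_trip_identity(self, n_frames, h, w, seed):
        rng = np.random.default_rng(seed)
        stack = ImageStack(rng.uniform(size=(n_frames, h, w)), 1.0)
        back = snapshots_to_stack(fd.stack_to_snapshots(stack))
        assert np.array_equal(back.data, stack.data)
        assert back.dt == stack.dt

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match="3 frames"):
            fd.stack_to_snapshots(ImageStack(np.zeros((2, 4, 4)), 1.0))


class TestOptimalRank:
    def test_rank_one_outer_product(self):
        u, v = np.arange(1, 50.0), np.arange(1, 20.0)
        s = np.linalg.svd(np.outer(u, v), compute_uv=False)
        assert fd.optimal_rank(s, 49, 19) == 1

    def test_pure_noise_rarely_exceeds_two(self):
        # Monte-Carlo calibration: iid Gaussian matrices, 200 columns
        hits = 0
        rng = np.random.default_rng(99)
        for _ in range(100):
            s = np.linalg.svd(rng.normal(size=(400, 200)), compute_uv=False)
            if fd.optimal_rank(s, 400, 200) <= 2:
                hits += 1
        assert hits >= 95

    def test_recovers_three_modes_under_noise(self):
        # 2% Gaussian noise on the static scene: the hard threshold keeps
        # exactly the three kinetic components
        scene = fd.default_scene("basic", noise=fd.NoiseParams(model="gaussian", sigma=0.02), seed=4)
        stack, _ = fd.render_stack(scene)
        pair = fd.stack_to_snapshots(stack)
        s = np.linalg.svd(pair.X, compute_uv=False)
        assert fd.optimal_rank(s, *pair.X.shape) == 3

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fd.optimal_rank(np.array([]), 4, 4)

    def test_threshold_coefficient_square_case(self):
        # published approximation at beta = 1
        assert gavish_donoho_omega(1.0) == pytest.approx(2.858, abs=5e-3)


class TestFit:
    def test_uniform_decay_single_eigenvalue(self):
        model = fd.fit(decay_stack(0.9, n=12), rank=1)
        assert model.lam[0] == pytest.approx(0.9, abs=1e-12)
        assert model.omega[0].real == pytest.approx(np.log(0.9), abs=1e-12)

    def test_static_stack_identity_dynamics(self):
        frames = np.ones((10, 3, 3)) * 7.0
        model = fd.fit(ImageStack(frames, 2.0), rank=1)
        assert model.lam[0] == pytest.approx(1.0, abs=1e-12)
        assert model.omega[0] == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_sim_recovers_model_eigenvalues(self, rates, basic_model):
        # oracle: analytic eigenvalues of the generating kinetic system
        truth = np.sort(fd.eigenvalues(rates).as_array())
        fitted = np.sort(model_real_omegas(basic_model))
        np.testing.assert_allclose(fitted, truth, atol=1e-6)

    def test_modes_sorted_slowest_first(self, basic_model):
        mags = np.abs(basic_model.omega)
        assert np.all(np.diff(mags) >= -1e-15)

    def test_projected_modes_same_eigenvalues(self, basic_stack):
        stack, _ = basic_stack
        exact = fd.fit(stack, rank=3)
        proj = fd.fit(stack, rank=3, exact_modes=False)
        np.testing.assert_allclose(np.sort(exact.lam.real), np.sort(proj.lam.real), atol=1e-10)

    def test_brute_force_propagator_cross_check(self):
        # independent oracle: eigenvalues of the full least-squares propagator
        # A = X' X^+ computed without the truncation machinery
        rng = np.random.default_rng(1)
        rates = fd.RateConstants(0.01, 0.02, 0.005, 0.3)
        small = render_small(rates, rng)
        pair = fd.stack_to_snapshots(small)
        A = pair.X_prime @ np.linalg.pinv(pair.X, rcond=1e-10)
        brute = np.linalg.eigvals(A)
        brute = np.sort(brute[np.abs(brute) > 1e-6].real)
        model = fd.fit(small, rank=3)
        np.testing.assert_allclose(np.sort(model.lam.real), brute, atol=1e-8)

    def test_spectrum_invariant_under_pixel_permutation(self, rates):
        rng = np.random.default_rng(2)
        small = render_small(rates, rng)
        model = fd.fit(small, rank=3)
        perm = rng.permutation(small.data[0].size)
        shuffled = small.data.reshape(small.n_frames, -1)[:, perm].reshape(small.data.shape)
        model_p = fd.fit(ImageStack(shuffled, small.dt), rank=3)
        np.testing.assert_allclose(
            np.sort(model.lam.real), np.sort(model_p.lam.real), atol=1e-9
        )

    def test_conjugate_pair_closure_oscillatory(self):
        model = fd.fit(oscillating_stack(), rank=3)
        lam = np.sort_complex(model.lam)
        assert np.allclose(np.sort_complex(lam.conj()), lam, atol=1e-9)
        # the complex pair carries the generating frequency and decay
        osc = model.omega[np.abs(model.omega.imag) > 1e-6]
        assert len(osc) == 2
        assert osc[0].real == pytest.approx(-0.01, abs=1e-8)
        assert abs(osc[0].imag) == pytest.approx(0.3, abs=1e-8)

    def test_zero_stack_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fd.fit(ImageStack(np.zeros((5, 2, 2)), 1.0))

    def test_aggregate_rate_recovery_under_noise(self):
        # slowest omega within 25% of -k2 across seeds at 2% noise
        devs = []
        for seed in range(20):
            scene = fd.default_scene(
                "basic", n_frames=150,
                noise=fd.NoiseParams(model="gaussian", sigma=0.02), seed=seed,
            )
            stack, _ = fd.render_stack(scene)
            model = fd.fit(stack, rank=3)
            devs.append(abs(model.omega[0].real - (-0.005)) / 0.005)
        assert max(devs) < 0.25


class TestRescale:
    def test_identity_eigenvalue(self):
        assert fd.rescale(np.array([1.0]), 5.0)[0] == 0.0

    def test_printed_slow_mode(self):
        # lambda = 0.996257 at 1 s/frame -> omega = -0.00375 /s
        om = fd.rescale(np.array([0.996257]), 1.0)[0]
        assert om.real == pytest.approx(-0.00375, abs=5e-7)
        assert round(0.996257, 3) == 0.996

    def test_log_linearity_in_dt(self):
        om = fd.rescale(np.array([np.exp(-0.015)]), 3.0)[0]
        assert om.real == pytest.approx(-0.005, rel=1e-12)

    def test_zero_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="lambda = 0"):
            fd.rescale(np.array([0.0]), 1.0)

    def test_negative_axis_warns(self):
        with pytest.warns(UserWarning, match="alias"):
            fd.rescale(np.array([-0.5 + 0j]), 1.0)


class TestReconstructPredict:
    def test_first_frame_is_amplitude_projection(self, basic_stack, basic_model):
        stack, _ = basic_stack
        rec0 = fd.reconstruct(basic_model, frames=[0]).data[0]
        np.testing.assert_allclose(rec0, stack.data[0], atol=1e-7 * stack.data.max())

    def test_exact_rank_recovery(self, basic_stack, basic_model):
        stack, _ = basic_stack
        rec = fd.reconstruct(basic_model, frames="all")
        err = np.abs(rec.data - stack.data).max()
        assert err < 1e-8 * stack.data.max()

    def test_discrete_continuous_agreement(self, basic_model):
        idx = np.array([0, 5, 50, 299])
        disc = fd.reconstruct(basic_model, frames=idx)
        cont = reconstruct_continuous(basic_model, idx * basic_model.dt)
        np.testing.assert_allclose(disc.data, cont.data, atol=1e-10 * disc.data.max())

    def test_reconstruction_is_real_to_tolerance(self, basic_model):
        idx = np.arange(0, 300, 10)
        dynamics = basic_model.lam[:, None] ** idx[None, :] * basic_model.b[:, None]
        complex_frames = (basic_model.Phi @ dynamics).T
        rel_imag = np.abs(complex_frames.imag).max() / np.abs(complex_frames.real).max()
        assert rel_imag < 1e-8

    def test_denoising_beats_noisy_input(self, noisy_stack):
        stack, gt = noisy_stack
        model = fd.fit(stack, rank="optimal")
        rec = fd.reconstruct(model, frames="all")
        assert fd.psnr(gt.clean, rec) > fd.psnr(gt.clean, stack)

    def test_extrapolation_matches_analytic_future(self, rates):
        rng = np.random.default_rng(8)
        full = render_small(rates, rng, n_frames=160)
        first100 = ImageStack(full.data[:100], full.dt)
        model = fd.fit(first100, rank=3)
        pred = fd.predict(model, 60, n_fitted=100)
        truth = full.data[150]
        err = np.abs(pred.data[50] - truth).max() / truth.max()
        assert err < 1e-6

    def test_predict_one_step_uniform_decay(self):
        stack = decay_stack(0.9, n=10)
        model = fd.fit(stack, rank=1)
        nxt = fd.predict(model, 1, n_fitted=10)
        np.testing.assert_allclose(nxt.data[0], stack.data[-1] * 0.9, atol=1e-10)

    def test_growing_mode_warns(self):
        stack = decay_stack(1.05, n=10)
        model = fd.fit(stack, rank=1)
        with pytest.warns(UserWarning, match="growing"):
            fd.predict(model, 1, n_fitted=10)

    def test_static_stack_prediction_constant(self):
        frames = np.ones((8, 3, 3)) * 4.0
        model = fd.fit(ImageStack(frames, 1.0), rank=1)
        np.testing.assert_allclose(fd.predict(model, 3, n_fitted=8).data, 4.0, atol=1e-10)


def test_model_archive_round_trip(tmp_path, basic_model):
    from flipdmd.dmd import load_model, save_model

    save_model(basic_model, tmp_path / "model")
    loaded = load_model(tmp_path / "model")
    np.testing.assert_array_equal(loaded.Phi, basic_model.Phi)
    np.testing.assert_array_equal(loaded.lam, basic_model.lam)
    assert loaded.dt == basic_model.dt
    assert loaded.image_shape == basic_model.image_shape


# ---------------------------------------------------------------------------
# helpers

def model_real_omegas(model):
    assert np.abs(model.omega.imag).max() < 1e-9
    return model.omega.real


def render_small(rates, rng, n_frames=80):
    """A 24x24 three-compartment stack (fast fixture for oracle tests)."""
    from flipdmd.compartment import trajectory

    times = np.arange(n_frames) * 1.0
    traj = trajectory(rates, fd.CompartmentState(200.0, 100.0, 100.0), times)
    h = w = 24
    yy, xx = np.mgrid[0:h, 0:w]
    nucleus = (xx - 6) ** 2 / 16 + (yy - 6) ** 2 / 9 <= 1
    agg = np.hypot(xx - 16, yy - 16) <= 3
    cyto = ~nucleus & ~agg
    data = np.zeros((n_frames, h, w))
    data[:, cyto] = traj[:, 1][:, None]
    data[:, nucleus] = traj[:, 2][:, None]
    data[:, agg] = traj[:, 0][:, None]
    return ImageStack(data, 1.0)


def oscillating_stack(n_frames=60, shape=(8, 8), seed=5):
    """Rank-3 real stack with one real decay and one damped oscillation."""
    rng = np.random.default_rng(seed)
    p1, p2, p3 = rng.uniform(0.5, 1.5, size=(3, *shape))
    t = np.arange(n_frames)
    frames = (
        p1[None] * (np.exp(-0.01 * t) * np.cos(0.3 * t))[:, None, None]
        + p2[None] * (np.exp(-0.01 * t) * np.sin(0.3 * t))[:, None, None]
        + p3[None] * np.exp(-0.005 * t)[:, None, None]
    )
    return ImageStack(frames, 1.0)
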