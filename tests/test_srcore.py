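"""Forward/backward operators, TV prior and the SR iteration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petsr
from petsr.core import GatedSequence, Image2D, MotionField, PSFModel
from petsr.srcore import (
    SRConfig,
    downsample,
    gaussian_blur,
    invert_mvf,
    moco,
    run_sr,
    sr_step,
    static_image,
    tv,
    tv_gradient,
    upsample,
    warp_image,
)


class TestWarp:
    def test_zero_field_is_identity(self):
        rng = np.random.default_rng(0)
        img = Image2D(rng.random((12, 12)), 0.1)
        out = warp_image(img, MotionField.zero((12, 12), 0.1))
        np.testing.assert_allclose(out.data, img.data, atol=1e-14)

    def test_constant_image_unchanged_by_any_field(self):
        img = Image2D(np.full((10, 10), 2.5), 0.1)
        rng = np.random.default_rng(1)
        M = MotionField(rng.normal(0, 3, (10, 10)), rng.normal(0, 3, (10, 10)), 0.1)
        out = warp_image(img, M)
        np.testing.assert_allclose(out.data, 2.5, atol=1e-12)

    def test_integer_shift_matches_index_roll(self):
        rng = np.random.default_rng(2)
        a = rng.random((16, 16))
        M = MotionField(np.full((16, 16), 2.0), np.zeros((16, 16)), 0.1)
        out = warp_image(Image2D(a, 0.1), M)
        # out(y, x) = a(y, x+2) away from the right border
        np.testing.assert_allclose(out.data[:, :-2], a[:, 2:], atol=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            warp_image(Image2D(np.zeros((4, 4)), 0.1), MotionField.zero((5, 5), 0.1))


class TestInvert:
    def test_negation_and_involution(self):
        rng = np.random.default_rng(3)
        M = MotionField(rng.normal(size=(8, 8)), rng.normal(size=(8, 8)), 0.1)
        Mi = invert_mvf(M)
        np.testing.assert_array_equal(Mi.u, -M.u)
        np.testing.assert_array_equal(invert_mvf(Mi).u, M.u)

    def test_warp_then_inverse_warp_roundtrip(self, default_truth):
        """For a smooth small field the negated field approximately inverts."""
        img = default_truth.reference
        M = default_truth.true_mvfs[8]  # max contraction, ~1.8 px peak
        back = warp_image(warp_image(img, M), invert_mvf(M))
        rmse = np.sqrt(np.mean((back.data - img.data) ** 2))
        assert rmse < 0.03 * np.ptp(img.data)


class TestResampling:
    def test_factor_one_is_identity(self):
        img = Image2D(np.arange(16.0).reshape(4, 4), 0.1)
        np.testing.assert_array_equal(downsample(img, 1).data, img.data)
        np.testing.assert_array_equal(upsample(img, 1).data, img.data)

    def test_constant_preserved_both_ways(self):
        img = Image2D(np.full((8, 8), 3.3), 0.1)
        np.testing.assert_allclose(downsample(img, 2).data, 3.3, atol=1e-12)
        np.testing.assert_allclose(upsample(img, 2).data, 3.3, atol=1e-12)

    def test_checkerboard_block_mean(self):
        board = np.indices((4, 4)).sum(axis=0) % 2.0
        out = downsample(Image2D(board, 0.1), 2)
        np.testing.assert_allclose(out.data, 0.5, atol=1e-14)
        assert out.spacing == pytest.approx(0.2)

    def test_upsample_halves_spacing(self):
        img = Image2D(np.random.default_rng(0).random((6, 6)), 0.2)
        up = upsample(img, 2)
        assert up.shape == (12, 12)
        assert up.spacing == pytest.approx(0.1)

    def test_invalid_factor_rejected(self):
        img = Image2D(np.zeros((4, 4)), 0.1)
        with pytest.raises(ValueError):
            downsample(img, 0)
        with pytest.raises(ValueError):
            upsample(img, -2)


class TestGaussianBlur:
    def test_impulse_response_has_nominal_fwhm(self):
        from scipy.optimize import curve_fit

        img = np.zeros((151, 151))
        img[75, 75] = 1.0
        out = gaussian_blur(Image2D(img, 0.1), PSFModel(1.5))
        row = out.data[75]
        x = (np.arange(151) - 75.0) * 0.1

        def g(x, a, s):
            return a * np.exp(-(x**2) / (2 * s**2))

        (a, s), _ = curve_fit(g, x, row, p0=(row.max(), 0.6))
        fwhm = 2 * np.sqrt(2 * np.log(2)) * s
        assert fwhm == pytest.approx(1.5, rel=0.02)

    def test_constant_unchanged_and_mass_preserved(self):
        img = Image2D(np.full((32, 32), 4.0), 0.1)
        np.testing.assert_allclose(gaussian_blur(img, PSFModel(1.5)).data, 4.0, atol=1e-9)
        imp = np.zeros((64, 64))
        imp[32, 32] = 1.0
        out = gaussian_blur(Image2D(imp, 0.2), PSFModel(1.5))
        assert out.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            PSFModel(-1.0)


class TestMoco:
    def test_identity_fields_give_upsampled_mean(self, noiseless_gated):
        zero = [
            MotionField.zero(noiseless_gated.shape, noiseless_gated.spacing, i)
            for i in range(len(noiseless_gated))
        ]
        out = moco(noiseless_gated, zero, 2)
        expected = upsample(
            Image2D(noiseless_gated.as_array().mean(axis=0), noiseless_gated.spacing), 2
        )
        np.testing.assert_allclose(out.data, expected.data, atol=1e-12)

    def test_single_frame_zero_field_is_upsampled_frame(self, noiseless_gated):
        seq = GatedSequence([noiseless_gated[0]])
        out = moco(seq, [MotionField.zero(seq.shape, seq.spacing)], 2)
        np.testing.assert_allclose(out.data, upsample(seq[0], 2).data, atol=1e-12)

    def test_true_fields_undo_motion_blur(self, default_truth, noiseless_gated):
        """MoCo is far closer to the motion-free degraded reference than static."""
        mo = moco(noiseless_gated, default_truth.true_mvfs, 2)
        st = static_image(noiseless_gated, 2)
        target = upsample(
            gaussian_blur(downsample(default_truth.reference, 2), PSFModel(1.5)), 2
        )
        rmse_mo = np.sqrt(np.mean((mo.data - target.data) ** 2))
        rmse_st = np.sqrt(np.mean((st.data - target.data) ** 2))
        assert rmse_mo < 0.5 * rmse_st

    def test_length_mismatch_rejected(self, noiseless_gated):
        with pytest.raises(ValueError):
            moco(noiseless_gated, [], 2)


class TestTV:
    def test_constant_image_has_zero_tv(self):
        assert tv(np.full((9, 9), 3.0)) == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(min_value=-5.0, max_value=5.0))
    def test_homogeneity(self, a):
        rng = np.random.default_rng(11)
        H = rng.random((7, 7))
        assert tv(a * H) == pytest.approx(abs(a) * tv(H), rel=1e-9, abs=1e-9)

    def test_vertical_unit_step_sums_to_row_count(self):
        H = np.zeros((10, 8))
        H[:, 4:] = 1.0
        assert tv(H) == pytest.approx(10.0)

    def test_gradient_matches_finite_differences(self):
        """tv_gradient equals minus the numerical derivative of smoothed TV."""
        rng = np.random.default_rng(5)
        H = rng.random((8, 8))
        eps = 0.1

        def tv_eps(a):
            gy = np.zeros_like(a)
            gx = np.zeros_like(a)
            gy[:-1, :] = a[1:, :] - a[:-1, :]
            gx[:, :-1] = a[:, 1:] - a[:, :-1]
            return np.sqrt(gy**2 + gx**2 + eps**2).sum()

        analytic = tv_gradient(H, eps)
        h = 1e-6
        for idx in [(0, 0), (3, 4), (7, 7), (5, 0), (0, 6), (4, 4)]:
            Hp = H.copy()
            Hp[idx] += h
            Hm = H.copy()
            Hm[idx] -= h
            numeric = -(tv_eps(Hp) - tv_eps(Hm)) / (2 * h)
            assert analytic[idx] == pytest.approx(numeric, abs=1e-6)

    def test_constant_and_ramp_have_vanishing_gradient(self):
        assert np.allclose(tv_gradient(np.full((8, 8), 2.0), 1e-3), 0.0)
        ramp = np.tile(np.arange(16.0), (16, 1))
        g = tv_gradient(ramp, 1e-9)
        assert np.abs(g[4:-4, 4:-4]).max() < 1e-6

    def test_disk_indicator_gradient_concentrates_on_boundary(self):
        yy, xx = np.indices((16, 16))
        disk = (np.hypot(yy - 7.5, xx - 7.5) < 4.5).astype(float)
        g = tv_gradient(disk, 1e-6)
        interior = np.hypot(yy - 7.5, xx - 7.5) < 2.5
        assert np.abs(g[interior]).max() < 1e-6
        assert np.abs(g).max() > 0.5


class TestSRIteration:
    def _trivial_setup(self):
        rng = np.random.default_rng(7)
        H = Image2D(rng.random((8, 8)), 0.1)
        gated = GatedSequence([H.copy(), H.copy()])
        mvfs = [MotionField.zero((8, 8), 0.1, i) for i in range(2)]
        cfg = SRConfig(lambda_tv=0.0, psf=PSFModel(0.0), factor=1)
        return H, gated, mvfs, cfg

    def test_consistent_data_is_fixed_point(self):
        H, gated, mvfs, cfg = self._trivial_setup()
        Hn, rmse = sr_step(H, gated, mvfs, cfg)
        np.testing.assert_allclose(Hn.data, H.data, atol=1e-12)
        assert rmse == pytest.approx(0.0, abs=1e-12)

    def test_starting_at_truth_gives_negligible_data_rmse(self, default_truth, noiseless_gated):
        cfg = SRConfig(psf=PSFModel(1.5), factor=2)
        _, rmse = sr_step(default_truth.reference, noiseless_gated, default_truth.true_mvfs, cfg)
        assert rmse < 0.01 * np.ptp(default_truth.reference.data)

    def test_one_step_from_moco_decreases_data_rmse(self, default_truth, noiseless_gated):
        cfg = SRConfig(psf=PSFModel(1.5), factor=2)
        H0 = moco(noiseless_gated, default_truth.true_mvfs, 2)
        H1, rmse0 = sr_step(H0, noiseless_gated, default_truth.true_mvfs, cfg)
        _, rmse1 = sr_step(H1, noiseless_gated, default_truth.true_mvfs, cfg)
        assert rmse1 < rmse0

    def test_converged_input_stops_within_two_iterations(self):
        H, gated, mvfs, cfg = self._trivial_setup()
        res = run_sr(gated, mvfs, cfg)
        assert res.iterations_run <= 2
        assert len(res.rmse_trace) == res.iterations_run

    def test_sr_beats_moco_against_truth(self, default_truth, noiseless_gated):
        res = run_sr(noiseless_gated, default_truth.true_mvfs, SRConfig())
        truth_img = default_truth.reference.data
        rmse_sr = np.sqrt(np.mean((res.H.data - truth_img) ** 2))
        rmse_mo = np.sqrt(np.mean((res.H_init.data - truth_img) ** 2))
        assert rmse_sr < rmse_mo
        assert res.rmse_trace[-1] < res.rmse_trace[0]
        assert res.iterations_run <= 200

    def test_total_counts_conserved(self, default_truth, noiseless_gated):
        res = run_sr(noiseless_gated, default_truth.true_mvfs, SRConfig())
        assert res.H.data.sum() == pytest.approx(res.H_init.data.sum(), rel=0.02)

    def test_divergence_aborts_with_diagnostic(self):
        rng = np.random.default_rng(0)
        gated = GatedSequence([Image2D(rng.random((4, 4)), 0.2) for _ in range(2)])
        mvfs = [MotionField.zero((8, 8), 0.1, i) for i in range(2)]
        cfg = SRConfig(
            lambda_tv=0.0, psf=PSFModel(0.0), factor=2,
            step_size=50.0, max_iters=100, stop_rel_change=1e-4,
        )
        with pytest.raises(RuntimeError, match="diverged"):
            run_sr(gated, mvfs, cfg)
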