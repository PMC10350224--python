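"""MIP, bead detection, FWHM estimation, RI conversion, deconvolution, SNR."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from dualsweep import (
    bead_fwhm,
    convert_fwhm,
    detect_beads,
    mip,
    richardson_lucy,
    snr,
)
from dualsweep.psf import FWHM_PER_SIGMA


def gaussian_bead(shape=(33, 33, 33), sigma=2.0, amplitude=1000.0, floor=0.0):
    vol = np.zeros(shape)
    vol[tuple(s // 2 for s in shape)] = 1.0
    vol = gaussian_filter(vol, sigma)
    return floor + amplitude * vol / vol.max()


class TestMip:
    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(0)
        stack = rng.integers(0, 1000, size=(5, 7, 6))
        for axis in range(3):
            expected = np.empty([s for i, s in enumerate(stack.shape) if i != axis])
            it = np.ndindex(*expected.shape)
            for idx in it:
                full = list(idx)
                full.insert(axis, slice(None))
                expected[idx] = max(stack[tuple(full)])
            assert np.array_equal(mip(stack, axis), expected)

    def test_single_bright_voxel_projects(self):
        stack = np.zeros((4, 5, 6))
        stack[2, 3, 4] = 9.0
        assert mip(stack, 0)[3, 4] == 9.0

    def test_empty_and_bad_axis_rejected(self):
        with pytest.raises(ValueError):
            mip(np.empty((0, 3, 3)))
        with pytest.raises(ValueError):
            mip(np.zeros((3, 3, 3)), axis=5)


class TestDetectBeads:
    def test_empty_stack_no_detections(self):
        assert len(detect_beads(np.zeros((10, 10, 10)), threshold=5.0)) == 0

    def test_two_separated_beads_found(self):
        stack = np.zeros((40, 40, 40))
        stack[10, 20, 20] = 1.0
        stack[30, 20, 20] = 1.0
        stack = gaussian_filter(stack, 1.5) * 1e4
        peaks = detect_beads(stack, threshold=50.0, min_separation=5)
        assert len(peaks) == 2
        assert sorted(p[0] for p in peaks) == [10, 30]

    def test_peak_within_one_voxel_of_truth(self):
        stack = gaussian_bead((31, 31, 31), 2.0, 500.0)
        peaks = detect_beads(stack, threshold=100.0, min_separation=3)
        assert len(peaks) == 1
        assert np.all(np.abs(peaks[0] - 15) <= 1)


class TestBeadFwhm:
    def test_known_sigma_recovered(self):
        # oracle: 2.3548 * 2.0 * 0.2 um
        m = bead_fwhm(gaussian_bead(sigma=2.0), (16, 16, 16), 0.2)
        expected = FWHM_PER_SIGMA * 2.0 * 0.2
        assert m.fwhm_x_um == pytest.approx(expected, rel=0.01)
        assert m.ok

    def test_isotropic_bead_isotropic_fwhm(self):
        m = bead_fwhm(gaussian_bead(sigma=2.5), (16, 16, 16), 1.0)
        assert m.fwhm_x_um == pytest.approx(m.fwhm_y_um, rel=1e-3)
        assert m.fwhm_x_um == pytest.approx(m.fwhm_z_um, rel=1e-3)

    @pytest.mark.parametrize("sigma", [1.5, 2.0, 3.0])
    def test_noise_free_bias_below_one_percent(self, sigma):
        m = bead_fwhm(gaussian_bead(sigma=sigma, amplitude=5000.0), (16, 16, 16), 1.0)
        expected = FWHM_PER_SIGMA * sigma
        for got in (m.fwhm_x_um, m.fwhm_y_um, m.fwhm_z_um):
            assert abs(got - expected) / expected < 0.01

    def test_poisson_noise_bias_below_five_percent(self):
        """Estimator *bias* at peak ~100 counts: mean over fixed-seed draws."""
        rng = np.random.default_rng(42)
        clean = gaussian_bead(sigma=2.0, amplitude=100.0, floor=10.0)
        expected = FWHM_PER_SIGMA * 2.0
        fits = []
        for _ in range(20):
            noisy = rng.poisson(clean).astype(float)
            m = bead_fwhm(noisy, (16, 16, 16), 1.0)
            if m.ok:
                fits.extend([m.fwhm_x_um, m.fwhm_y_um, m.fwhm_z_um])
        assert abs(np.mean(fits) - expected) / expected < 0.05

    def test_fit_failure_flagged(self):
        m = bead_fwhm(np.zeros((21, 21, 21)), (10, 10, 10), 1.0)
        assert not m.ok
        assert m.fit_quality == 0.0

    def test_centroid_outside_rejected(self):
        with pytest.raises(ValueError):
            bead_fwhm(np.zeros((10, 10, 10)), (20, 5, 5), 1.0)


class TestConvertFwhm:
    def test_water_to_high_index_value(self):
        assert convert_fwhm(0.97, 1.33, 1.56) == pytest.approx(0.83, abs=5e-3)

    def test_identity_and_round_trip(self):
        assert convert_fwhm(1.23, 1.4, 1.4) == 1.23
        assert convert_fwhm(convert_fwhm(1.23, 1.33, 1.56), 1.56, 1.33) == (
            pytest.approx(1.23, rel=1e-12)
        )

    def test_invalid_indices_rejected(self):
        with pytest.raises(ValueError):
            convert_fwhm(1.0, 0.5, 1.33)


def _naive_rl(image, psf, n_iter):
    """Independent reference Richardson-Lucy iteration (direct convolution)."""
    from scipy.signal import fftconvolve

    est = np.full_like(image, image.mean(), dtype=float)
    mirror = psf[::-1, ::-1, ::-1]
    for _ in range(n_iter):
        conv = fftconvolve(est, psf, mode="same")
        ratio = image / np.clip(conv, 1e-12, None)
        est = est * fftconvolve(ratio, mirror, mode="same")
    return est


class TestRichardsonLucy:
    def test_delta_psf_identity(self):
        img = gaussian_bead(sigma=2.0)
        psf = np.zeros((5, 5, 5))
        psf[2, 2, 2] = 1.0
        out = richardson_lucy(img, psf, 5)
        assert np.allclose(out, img, atol=1e-8)

    def test_monotone_sharpening_and_flux_conservation(self):
        blurred = gaussian_bead(sigma=2.5, amplitude=1000.0)
        psf = gaussian_bead((17, 17, 17), sigma=2.0, amplitude=1.0)
        widths = []
        for it in range(1, 11):
            dec = richardson_lucy(blurred, psf, it)
            assert abs(dec.sum() / blurred.sum() - 1.0) < 0.01
            widths.append(bead_fwhm(dec, (16, 16, 16), 1.0).fwhm_x_um)
        assert all(b <= a + 1e-6 for a, b in zip(widths, widths[1:]))
        assert widths[-1] < bead_fwhm(blurred, (16, 16, 16), 1.0).fwhm_x_um

    def test_matches_reference_iteration(self):
        """Oracle: independent naive RL loop on the same inputs."""
        blurred = gaussian_bead((17, 17, 17), sigma=1.8, amplitude=200.0, floor=1.0)
        psf = gaussian_bead((9, 9, 9), sigma=1.5, amplitude=1.0)
        psf = psf / psf.sum()
        ours = richardson_lucy(blurred, psf, 5)
        ref = _naive_rl(blurred, psf, 5)
        m_ours = bead_fwhm(ours, (8, 8, 8), 1.0)
        m_ref = bead_fwhm(ref, (8, 8, 8), 1.0)
        assert m_ours.fwhm_x_um == pytest.approx(m_ref.fwhm_x_um, rel=0.05)

    def test_bad_psf_rejected(self):
        with pytest.raises(ValueError):
            richardson_lucy(np.ones((5, 5, 5)), np.zeros((3, 3, 3)), 5)
        with pytest.raises(ValueError):
            richardson_lucy(np.ones((5, 5, 5)), np.ones((3, 3, 3)), 0)


class TestSnr:
    def test_constructed_grid_value(self):
        # oracle: (300 - 100) / 10 = 20 by hand on a constructed image
        rng = np.random.default_rng(1)
        img = np.empty(10_000)
        img[:5000] = 300.0
        bg = rng.normal(100.0, 10.0, 5000)
        bg = (bg - bg.mean()) / bg.std(ddof=1) * 10.0 + 100.0  # exact moments
        img[5000:] = bg
        fg_mask = np.zeros(10_000, bool)
        fg_mask[:5000] = True
        res = snr(img, fg_mask, ~fg_mask)
        assert res.snr == pytest.approx(20.0, rel=1e-9)

    def test_identical_statistics_near_zero(self):
        rng = np.random.default_rng(2)
        img = rng.normal(100.0, 5.0, 20_000)
        mask = np.zeros(20_000, bool)
        mask[:10_000] = True
        assert abs(snr(img, mask, ~mask).snr) < 0.05

    def test_homogeneity_after_offset_removal(self):
        rng = np.random.default_rng(3)
        img = rng.normal(50.0, 5.0, 10_000)
        img[:3000] += 100.0
        mask = np.zeros(10_000, bool)
        mask[:3000] = True
        base = snr(img, mask, ~mask).snr
        scaled = snr(3.0 * img, mask, ~mask).snr
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_mask_validation(self):
        img = np.ones(100)
        mask = np.zeros(100, bool)
        mask[:10] = True
        with pytest.raises(ValueError):
            snr(img, mask, mask)  # overlapping
        with pytest.raises(ValueError):
            snr(img, np.zeros(100, bool), ~mask)
        with pytest.raises(ZeroDivisionError):
            snr(img, mask, ~mask)  # constant background
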