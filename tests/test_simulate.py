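"""Forward model: pattern rendering, PSF rasterisation, blur, Poisson sampling."""

import numpy as np
import pytest

from srsaxs._convolve import reflect_convolve
from srsaxs.simulate import (
    DetectorFrame,
    GroundTruthPattern,
    PSFModel,
    blur,
    default_psf_set,
    grid_shifts,
    lr_shape,
    render_ground_truth,
    render_psf,
    psf_support_for,
    sample_frame,
    simulate_acquisition,
)


def _single_ring(radius=30.0, width=0.7, amp=1.0, grid=129, **kw):
    c = (grid - 1) / 2.0
    return GroundTruthPattern(
        rings=((radius, width, amp),), center=(c, c), grid_shape=(grid, grid), **kw
    )


class TestRenderGroundTruth:
    def test_lorentzian_peak_value_at_mode(self):
        pat = _single_ring(radius=30.0, width=0.7, amp=1.0)
        img = render_ground_truth(pat)
        # pixel exactly 30 px right of center lies on the ring
        assert img[64, 94] == pytest.approx(1.0)

    def test_two_ring_profile_has_two_maxima(self, doublet_native, doublet_native_gt):
        from srsaxs.geometry import azimuthal_integrate

        prof = azimuthal_integrate(doublet_native_gt, doublet_native.center)
        sel = (prof.bins >= 25) & (prof.bins <= 40)
        y = prof.intensity[sel]
        b = prof.bins[sel]
        peaks = [b[i] for i in range(1, len(y) - 1) if y[i] > y[i - 1] and y[i] > y[i + 1]]
        assert any(abs(p - 30) <= 1 for p in peaks)
        assert any(abs(p - 34) <= 1 for p in peaks)

    def test_background_and_beamstop_closed_form(self):
        pat = GroundTruthPattern(
            rings=((50.0, 0.5, 1.0),),  # far ring, negligible at rho=10
            background_coeff=1.0,
            beamstop_radius=5.0,
            center=(64.0, 64.0),
            grid_shape=(129, 129),
        )
        img = render_ground_truth(pat)
        ring_term = 1.0 * 0.5**2 / ((10 - 50) ** 2 + 0.5**2)
        assert img[64, 74] == pytest.approx(0.1 + ring_term, rel=1e-12)
        assert img[64, 66] == 0.0  # rho=2 < beamstop
        assert np.all(img >= 0) and np.all(np.isfinite(img))

    def test_ring_beyond_grid_warns(self):
        with pytest.warns(UserWarning, match="beyond the grid"):
            render_ground_truth(_single_ring(radius=500.0))

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthPattern(rings=((30, -1, 1),), center=(5, 5), grid_shape=(11, 11))
        with pytest.raises(ValueError):
            GroundTruthPattern(rings=(), center=(0, 0), grid_shape=(0, 0))


class TestRenderPSF:
    def test_zero_slit_is_gaussian(self):
        model = PSFModel(w_x=0.0, w_y=0.0, source_sigma=1.5)
        k = render_psf(model, 17)
        u = np.arange(-8, 9, dtype=float)
        g = np.exp(-(u**2) / (2 * 1.5**2))
        expected = np.outer(g, g)
        expected /= expected.sum()
        assert np.abs(k - expected).max() < 1e-9

    def test_zero_sigma_is_rectangle(self):
        model = PSFModel(w_x=5.0, w_y=5.0, source_sigma=0.0)
        k = render_psf(model, 11)
        row = k[5] / k[5].max()
        inside = np.abs(np.arange(-5, 6)) < 2.5
        assert np.all(row[inside] == row[inside][0])
        assert row[0] == 0.0  # outside the slit

    def test_matches_bruteforce_rectangle_gaussian_convolution(self):
        """Oracle: numerically integrate the Gaussian over the slit aperture
        at each sample point and compare with the erf closed form."""
        from scipy.integrate import quad

        w, s, support = 4.0, 1.0, 21
        centers = np.arange(-(support // 2), support // 2 + 1, dtype=float)
        oracle_1d = np.array([
            quad(lambda v: np.exp(-(v**2) / (2 * s**2)), u - w / 2, u + w / 2)[0]
            for u in centers
        ])
        oracle = np.outer(oracle_1d, oracle_1d)
        oracle /= oracle.sum()
        k = render_psf(PSFModel(w_x=w, w_y=w, source_sigma=s), support)
        assert np.abs(k / k.sum() - oracle).max() < 1e-6

    def test_separable_symmetric_unit_sum(self):
        model = PSFModel(w_x=3.0, w_y=5.0, source_sigma=0.8, flux_scale=2.5)
        k = render_psf(model, psf_support_for(model))
        assert k.sum() == pytest.approx(2.5, rel=1e-6)
        assert np.all(k >= 0)
        assert np.abs(k - k[::-1, ::-1]).max() < 1e-12  # symmetric about center
        # separability: rank-1
        s = np.linalg.svd(k, compute_uv=False)
        assert s[1] / s[0] < 1e-12

    def test_support_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            render_psf(PSFModel(w_x=10.0, w_y=10.0, source_sigma=2.0), 5)

    def test_default_set_flux_follows_slit_area(self):
        psfs = default_psf_set(3.0, source_sigma=1.0)
        assert len(psfs) == 6
        assert psfs[0].flux_scale == pytest.approx(1.0)
        for p in psfs:
            assert p.flux_scale == pytest.approx(p.w_x * p.w_y / 9.0)


class TestBlur:
    def test_delta_kernel_is_identity(self, rng):
        img = rng.random((40, 40))
        delta = np.zeros((5, 5))
        delta[2, 2] = 1.0
        assert np.abs(blur(img, delta) - img).max() < 1e-12

    def test_constant_image_scales_by_flux(self):
        img = np.full((30, 30), 2.0)
        k = render_psf(PSFModel(w_x=3, w_y=3, source_sigma=0.5, flux_scale=1.8), 9)
        out = blur(img, k)
        assert np.abs(out - 2.0 * 1.8).max() < 1e-9

    def test_linearity(self, rng):
        x1, x2 = rng.random((32, 32)), rng.random((32, 32))
        k = render_psf(PSFModel(w_x=2, w_y=4, source_sigma=0.7), 11)
        lhs = blur(3.0 * x1 + 0.5 * x2, k)
        rhs = 3.0 * blur(x1, k) + 0.5 * blur(x2, k)
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_flux_conservation_interior_pattern(self):
        # centered blob far from the edges: total flux preserved x flux_scale
        y, x = np.mgrid[:64, :64]
        img = np.exp(-(((y - 32) ** 2 + (x - 32) ** 2) / 50.0))
        k = render_psf(PSFModel(w_x=3, w_y=3, source_sigma=0.8, flux_scale=1.5), 11)
        assert blur(img, k).sum() == pytest.approx(1.5 * img.sum(), rel=1e-6)

    def test_smearing_shallows_doublet_valley(self, doublet_native, doublet_native_gt):
        from srsaxs.geometry import azimuthal_integrate

        k = render_psf(PSFModel(w_x=4, w_y=4, source_sigma=1.0), 15)
        blurred = blur(doublet_native_gt, k)
        def valley_depth(img):
            prof = azimuthal_integrate(img / img.sum(), doublet_native.center)
            sel = (prof.bins >= 28) & (prof.bins <= 36)
            y = prof.intensity[sel]
            return y.max() - y.min()
        assert valley_depth(blurred) < valley_depth(doublet_native_gt)

    def test_nan_rejected(self):
        img = np.ones((10, 10))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            blur(img, np.ones((3, 3)))


class TestSampleFrame:
    def test_zero_exposure_gives_zero_frame(self, rng):
        fr = sample_frame(np.ones((30, 30)), (1, 2), 3, 0.0, rng)
        assert fr.counts.sum() == 0

    def test_poisson_mean_matches_box_sum(self):
        # constant c=2, f=3, t=2 -> per-pixel mean 18c = 36
        img = np.full((302, 302), 2.0)
        fr = sample_frame(img, (0, 0), 3, 2.0, np.random.default_rng(7))
        n = fr.counts.size
        se = np.sqrt(36.0 / n)
        assert abs(fr.counts.mean() - 36.0) < 4 * se

    def test_seed_determinism(self):
        img = np.random.default_rng(0).random((60, 60)) * 10
        a = sample_frame(img, (1, 1), 3, 5.0, np.random.default_rng(42))
        b = sample_frame(img, (1, 1), 3, 5.0, np.random.default_rng(42))
        assert np.array_equal(a.counts, b.counts)

    def test_shift_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError, match="outside"):
            sample_frame(np.ones((30, 30)), (3, 0), 3, 1.0, rng)

    def test_point_aperture_decimates_cell_centers(self):
        img = np.arange(90.0 * 90).reshape(90, 90)
        fr = sample_frame(img, (0, 0), 3, 1e12, np.random.default_rng(0), aperture="point")
        n, m = lr_shape(img.shape, 3)
        expected = 9 * img[1::3, 1::3][:n, :m] * 1e12
        assert np.abs(fr.counts / expected - 1).max() < 1e-3  # Poisson rel noise ~1e-6

    def test_long_exposure_converges_to_ground_truth(self):
        # f=1, delta PSF: frame/t -> intensity pointwise as t grows
        img = np.random.default_rng(3).random((50, 50)) + 0.5
        errs = []
        for t in (1e2, 1e4, 1e6):
            fr = sample_frame(img, (0, 0), 1, t, np.random.default_rng(11))
            errs.append(np.abs(fr.counts / t - img).max())
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 5e-3


class TestSimulateAcquisition:
    def test_plain_single_frame(self, subpixel_doublet):
        psfs = default_psf_set(2.0)[:1]
        fs = simulate_acquisition(subpixel_doublet, psfs, 3, [(0, 0)], 1.0, 0)
        assert len(fs.frames) == 1 and fs.m == 1 and fs.protocol == "plain"

    def test_full_srsaxs_set_counts(self, subpixel_doublet):
        psfs = default_psf_set(2.0)
        fs = simulate_acquisition(subpixel_doublet, psfs, 3, grid_shifts(3), 1.0, 0)
        assert len(fs.frames) == 54 and fs.m == 6 and fs.protocol == "SrSAXS"

    def test_cmd_protocol_label(self, subpixel_doublet):
        psfs = default_psf_set(2.0)
        fs = simulate_acquisition(subpixel_doublet, psfs, 3, [(0, 0)], 9.0, 0)
        assert len(fs.frames) == 6 and fs.protocol == "CMD"

    def test_empty_inputs_rejected(self, subpixel_doublet):
        with pytest.raises(ValueError):
            simulate_acquisition(subpixel_doublet, [], 3, [(0, 0)], 1.0, 0)
        with pytest.raises(ValueError):
            simulate_acquisition(subpixel_doublet, default_psf_set(2.0), 3, [], 1.0, 0)

    def test_photon_conservation(self, doublet_native):
        """Expected frame total = t x flux x blurred-GT total over the field."""
        gt = render_ground_truth(doublet_native)
        model = PSFModel(w_x=3, w_y=3, source_sigma=0.5, flux_scale=1.4)
        blurred = blur(gt, render_psf(model, psf_support_for(model)))
        t = 50.0
        fr = sample_frame(blurred, (0, 0), 1, t, np.random.default_rng(5))
        lam_tot = t * blurred.sum()
        assert abs(fr.counts.sum() - lam_tot) < 5 * np.sqrt(lam_tot)

    def test_root_seed_reproducibility(self, subpixel_doublet):
        psfs = default_psf_set(2.0)[:2]
        a = simulate_acquisition(subpixel_doublet, psfs, 3, grid_shifts(3), 2.0, 99)
        b = simulate_acquisition(subpixel_doublet, psfs, 3, grid_shifts(3), 2.0, 99)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.counts, fb.counts)


def test_detector_frame_invariants():
    with pytest.raises(ValueError):
        DetectorFrame(counts=np.array([[-1]]), exposure=1.0, nominal_shift=(0, 0),
                      psf_id="p", f=1)
    with pytest.raises(ValueError):
        DetectorFrame(counts=np.ones((2, 2), int), exposure=1.0, nominal_shift=(3, 0),
                      psf_id="p", f=3)
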