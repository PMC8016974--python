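"""PSF descriptors: analytic profiles, oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selfipsf import ParticleModel, extract_features, locate_center, selfi_psf
from selfipsf.engine import selfi_radial_profile
from selfipsf.features import (
    CrossSectionProfile,
    DetectionError,
    area,
    averaged_cross_section,
    depth,
    inner_fwhm,
    outer_fwhm,
)

FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def make_profile(r, y):
    return CrossSectionProfile(r_nm=np.asarray(r, float), intensity=np.asarray(y, float), background=0.0)


def gaussian_profile(sigma=100.0, r_max=1000.0, step=1.0):
    r = np.arange(-r_max, r_max + step / 2, step)
    return make_profile(r, np.exp(-(r**2) / (2 * sigma**2)))


class TestProfileDescriptors:
    def test_gaussian_fwhm_analytic(self):
        prof = gaussian_profile(sigma=100.0)
        assert outer_fwhm(prof) == pytest.approx(FWHM_SIGMA * 100.0, rel=1e-4)

    def test_fwhm_scaling_invariance(self):
        prof = gaussian_profile()
        scaled = make_profile(prof.r_nm, 37.2 * prof.intensity)
        assert outer_fwhm(scaled) == pytest.approx(outer_fwhm(prof))

    def test_gaussian_has_no_dip(self):
        prof = gaussian_profile()
        assert np.isnan(inner_fwhm(prof))
        assert depth(prof) == 0.0

    def test_inverted_gaussian_dip_width_analytic(self):
        sigma_d = 80.0
        r = np.arange(-600.0, 600.5, 1.0)
        y = 1.0 - np.exp(-(r**2) / (2 * sigma_d**2))
        prof = make_profile(r, y)
        assert depth(prof) == pytest.approx(1.0)
        assert inner_fwhm(prof) == pytest.approx(FWHM_SIGMA * sigma_d, rel=1e-3)

    def test_rectangle_area_is_width(self):
        r = np.arange(-500.0, 500.5, 1.0)
        y = np.where(np.abs(r) <= 200.0, 3.0, 0.0)
        assert area(make_profile(r, y)) == pytest.approx(400.0, rel=0.01)

    def test_gaussian_area_analytic(self):
        prof = gaussian_profile(sigma=100.0, r_max=1500.0)
        assert area(prof) == pytest.approx(np.sqrt(2 * np.pi) * 100.0, rel=0.01)

    def test_ring_with_zero_centre_depth_one(self):
        r = np.arange(-500.0, 500.5, 1.0)
        y = np.exp(-((np.abs(r) - 250.0) ** 2) / (2 * 60.0**2))
        assert depth(make_profile(r, y)) == pytest.approx(1.0, abs=2e-4)

    def test_no_positive_maximum_raises(self):
        r = np.arange(-10.0, 10.5, 1.0)
        with pytest.raises(ValueError):
            outer_fwhm(make_profile(r, np.zeros_like(r)))


class TestLocateCenter:
    def _doughnut_image(self, cx_px, cy_px, stack, imaging, n_px=48):
        r_fine = np.linspace(0, 3200, 1024)
        prof = selfi_radial_profile(
            r_fine, ParticleModel(spacing_nm=154.9), stack, imaging, 455.0
        )
        c = np.arange(n_px) * imaging.pixel_pitch_nm
        xx, yy = np.meshgrid(c, c)
        rr = np.hypot(
            xx - cx_px * imaging.pixel_pitch_nm, yy - cy_px * imaging.pixel_pitch_nm
        )
        return np.interp(rr, r_fine, prof)

    def test_subpixel_doughnut_accuracy(self, stack, imaging):
        im = self._doughnut_image(20.3, 17.7, stack, imaging)
        cx, cy = locate_center(im)
        assert abs(cx - 20.3) < 0.1 and abs(cy - 17.7) < 0.1

    def test_whole_pixel_translation_equivariance(self, stack, imaging):
        im = self._doughnut_image(20.3, 17.7, stack, imaging)
        cx0, cy0 = locate_center(im)
        shifted = np.roll(np.roll(im, 3, axis=1), -2, axis=0)
        cx1, cy1 = locate_center(shifted)
        assert cx1 - cx0 == pytest.approx(3.0, abs=0.05)
        assert cy1 - cy0 == pytest.approx(-2.0, abs=0.05)

    def test_symmetric_gaussian_center_is_centroid(self):
        c = np.arange(48)
        xx, yy = np.meshgrid(c, c)
        im = np.exp(-((xx - 20.0) ** 2 + (yy - 22.0) ** 2) / (2 * 3.0**2))
        cx, cy = locate_center(im)
        assert cx == pytest.approx(20.0, abs=0.02)
        assert cy == pytest.approx(22.0, abs=0.02)

    def test_flat_image_raises(self):
        with pytest.raises(DetectionError):
            locate_center(np.ones((32, 32)))


class TestAveragedCrossSection:
    def test_rotationally_symmetric_image_angle_independent(self, stack, imaging):
        psf = selfi_psf(ParticleModel(spacing_nm=154.9), stack, imaging, 455.0)
        ctr = ((imaging.field_px - 1) / 2.0,) * 2
        p1 = averaged_cross_section(psf.frame(0), ctr, imaging.pixel_pitch_nm, n_angles=1)
        p16 = averaged_cross_section(psf.frame(0), ctr, imaging.pixel_pitch_nm, n_angles=16)
        assert np.allclose(p1.intensity, p16.intensity, atol=1e-2 * p16.intensity.max())

    def test_constant_image_flat_profile(self):
        im = np.full((40, 40), 7.0)
        prof = averaged_cross_section(im, (19.5, 19.5), 65.0)
        assert prof.background == pytest.approx(7.0)
        assert np.max(np.abs(prof.intensity)) < 1e-12

    def test_synthetic_ring_maxima_at_radius(self):
        rho0 = 520.0
        c = (np.arange(64) - 31.5) * 65.0
        xx, yy = np.meshgrid(c, c)
        rr = np.hypot(xx, yy)
        im = np.exp(-((rr - rho0) ** 2) / (2 * 80.0**2))
        prof = averaged_cross_section(im, (31.5, 31.5), 65.0, psf_radius_nm=400.0)
        half = len(prof.r_nm) // 2
        r_peak = prof.r_nm[half:][np.argmax(prof.intensity[half:])]
        assert abs(r_peak - rho0) <= 65.0

    def test_truncation_flag(self):
        im = np.random.default_rng(0).poisson(5.0, (20, 20)).astype(float)
        prof = averaged_cross_section(im, (9.5, 9.5), 65.0, r_max_nm=5000.0)
        assert "truncated" in prof.flags


class TestExtractFeatures:
    def test_oversampled_bruteforce_oracle(self, stack, imaging):
        """Default-step features match a 20x-oversampled profile within 0.5%."""
        psf = selfi_psf(ParticleModel(spacing_nm=154.9), stack, imaging, 455.0)
        frame = psf.frame(0)
        ctr = ((imaging.field_px - 1) / 2.0,) * 2
        fv = extract_features(frame, imaging.pixel_pitch_nm, center=ctr)
        dense = averaged_cross_section(
            frame, ctr, imaging.pixel_pitch_nm, step_nm=imaging.pixel_pitch_nm / 20.0
        )
        oracle = {
            "fwhm": outer_fwhm(dense),
            "ifwhm": inner_fwhm(dense),
            "area": area(dense),
            "depth": depth(dense),
        }
        for name, ref in oracle.items():
            assert fv.value(name) == pytest.approx(ref, rel=5e-3)

    @given(gain=st.floats(0.1, 50.0), offset=st.floats(0.0, 30.0))
    @settings(max_examples=15, deadline=None)
    def test_scale_and_offset_invariance(self, stack, imaging, gain, offset):
        psf = selfi_psf(ParticleModel(spacing_nm=154.9), stack, imaging, 455.0)
        frame = psf.frame(0) * 1e6
        ctr = ((imaging.field_px - 1) / 2.0,) * 2
        fv0 = extract_features(frame, imaging.pixel_pitch_nm, center=ctr)
        fv1 = extract_features(gain * frame + offset, imaging.pixel_pitch_nm, center=ctr)
        for name in ("fwhm", "ifwhm", "area", "depth"):
            assert fv1.value(name) == pytest.approx(fv0.value(name), rel=1e-6, nan_ok=True)

    def test_discretization_stability(self, optics, stack):
        """Features at 2x finer pixel pitch agree within 2%."""
        from selfipsf import ImagingSystem, OpticsConfig

        img1 = ImagingSystem.from_config(optics)
        img2 = ImagingSystem.from_config(
            OpticsConfig(pixel_pitch_nm=optics.pixel_pitch_nm / 2, field_px=2 * optics.field_px)
        )
        p = ParticleModel(spacing_nm=154.9)
        fv1 = extract_features(
            selfi_psf(p, stack, img1, 455.0).frame(0),
            img1.pixel_pitch_nm,
            center=((img1.field_px - 1) / 2.0,) * 2,
        )
        fv2 = extract_features(
            selfi_psf(p, stack, img2, 455.0).frame(0),
            img2.pixel_pitch_nm,
            center=((img2.field_px - 1) / 2.0,) * 2,
        )
        for name in ("fwhm", "ifwhm", "area", "depth"):
            assert fv1.value(name) == pytest.approx(fv2.value(name), rel=0.02)

    def test_depth_monotone_in_two_beam_contrast(self):
        """Filling a ring's centre monotonically reduces the dip contrast."""
        r = np.arange(-600.0, 600.5, 2.0)
        ring = np.exp(-((np.abs(r) - 250.0) ** 2) / (2 * 70.0**2))
        fill = np.exp(-(r**2) / (2 * 120.0**2))
        depths = [depth(make_profile(r, ring + c * fill)) for c in np.linspace(0, 1.5, 7)]
        assert all(b <= a + 1e-12 for a, b in zip(depths, depths[1:]))
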