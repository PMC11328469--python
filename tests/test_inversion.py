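"""Unwrapping, temporal harmonic, radial profile, Bessel fit, validity rule."""

import math

import numpy as np
import pytest

from cylmre import (
    ComplexWaveImage,
    DispersionPoint,
    SpringpotParams,
    WaveAcquisition,
    extract_radial_profile,
    fit_bessel,
    invert_series,
    synthesize_wave_series,
    temporal_harmonic,
    unwrap_phase,
    validate_frequency,
    wrap_phase,
)
from cylmre.bessel import j0_complex
from cylmre.errors import (
    EmptyProfileError,
    InvalidInputError,
    UndersampledError,
)
from cylmre.inversion import RadialProfile, estimate_center
from cylmre.springpot import springpot_modulus, wavenumber_from_modulus

from conftest import springpot_dispersion_oracle


class TestUnwrapPhase:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 1.2)
        out = unwrap_phase(img)
        np.testing.assert_allclose(out, img)

    def test_all_zero(self):
        out = unwrap_phase(np.zeros((16, 16)))
        np.testing.assert_array_equal(out, 0.0)

    def test_wrap_then_unwrap_recovers_smooth_field(self):
        """A 3-rad-peak smooth field wraps; unwrapping restores it up to a
        global 2 pi multiple."""
        yy, xx = np.mgrid[0:64, 0:64]
        phi = 3.0 * np.cos(0.25 * xx) * np.exp(-((yy - 32) / 30.0) ** 2)
        out = unwrap_phase(wrap_phase(phi))
        diff = out - phi
        offset = diff.flat[0]
        assert offset == pytest.approx(round(offset / (2 * math.pi)) * 2 * math.pi,
                                       abs=1e-9)
        np.testing.assert_allclose(diff, offset, atol=1e-9)

    def test_mod_2pi_consistency_with_mask(self):
        rng = np.random.default_rng(0)
        img = wrap_phase(rng.uniform(-10, 10, (32, 32)))
        mask = np.zeros((32, 32), bool)
        mask[8:24, 8:24] = True
        out = unwrap_phase(img, mask=mask)
        resid = np.mod(out - img, 2 * math.pi)
        resid = np.minimum(resid, 2 * math.pi - resid)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)
        # outside the mask the image is untouched
        np.testing.assert_array_equal(out[~mask], img[~mask])


class TestTemporalHarmonic:
    def test_dc_only_gives_zero(self):
        stack = np.repeat(np.random.default_rng(0).uniform(size=(1, 8, 8)), 4, axis=0)
        np.testing.assert_allclose(temporal_harmonic(stack), 0.0, atol=1e-12)

    def test_discrete_fourier_identity(self):
        """x_t = 2 cos(w t + 0.3) over 4 offsets -> modulus 2, phase 0.3."""
        t = 2 * np.pi * np.arange(4) / 4
        stack = (2.0 * np.cos(t + 0.3))[:, None, None] * np.ones((1, 3, 3))
        h = temporal_harmonic(stack)
        assert np.allclose(np.abs(h), 2.0)
        assert np.allclose(np.angle(h), 0.3)

    def test_undersampled_raises(self):
        with pytest.raises(UndersampledError):
            temporal_harmonic(np.zeros((2, 4, 4)))

    def test_round_trip_matches_bessel_field(self, midrange_params):
        f = 1700.0
        acq = WaveAcquisition(frequencies=(f,))
        series = synthesize_wave_series(midrange_params, acq, noise_sd=0.0, seed=0)
        unwrapped = np.stack([unwrap_phase(im, mask=acq.tube_mask())
                              for im in series.phase[f]])
        h = temporal_harmonic(unwrapped)
        k = wavenumber_from_modulus(springpot_modulus(midrange_params, f),
                                    acq.density, f)
        inside = acq.tube_mask()
        model = j0_complex(k * acq.radius_map())
        ratio = h[inside] / model[inside]
        assert np.std(np.abs(ratio)) / np.mean(np.abs(ratio)) < 1e-9


class TestRadialProfile:
    def _image(self, data, pixel=150e-6, f=1300.0):
        return ComplexWaveImage(data=data, frequency=f, pixel_size=pixel)

    def test_constant_image_constant_profile(self):
        img = self._image(np.full((64, 64), 2.0 + 1.0j))
        prof = extract_radial_profile(img, (31.5, 31.5), 3.5e-3)
        np.testing.assert_allclose(prof.u, 2.0 + 1.0j)

    def test_symmetric_field_binned_within_2pct(self):
        """Annular binning of J0(k r) reproduces J0 at the bin radius."""
        k = complex(2000.0, -300.0)
        yy, xx = np.mgrid[0:64, 0:64]
        r = np.hypot(yy - 31.5, xx - 31.5) * 150e-6
        img = self._image(j0_complex(k * r))
        prof = extract_radial_profile(img, (31.5, 31.5), 3.5e-3,
                                      bin_width=150e-6)
        model = j0_complex(k * prof.r)
        rel = np.abs(prof.u - model) / np.abs(model)
        assert rel.max() < 0.02

    def test_exact_mode_is_lossless(self):
        k = complex(3000.0, -500.0)
        yy, xx = np.mgrid[0:64, 0:64]
        r = np.hypot(yy - 31.5, xx - 31.5) * 150e-6
        img = self._image(j0_complex(k * r))
        prof = extract_radial_profile(img, (31.5, 31.5), 3.5e-3)
        np.testing.assert_allclose(prof.u, j0_complex(k * prof.r), rtol=1e-6)

    def test_pixel_count_conservation(self):
        img = self._image(np.ones((64, 64), complex))
        prof = extract_radial_profile(img, (31.5, 31.5), 3.5e-3)
        yy, xx = np.mgrid[0:64, 0:64]
        inside = np.hypot(yy - 31.5, xx - 31.5) * 150e-6 <= 3.5e-3
        assert prof.n_px.sum() == inside.sum()

    def test_empty_profile_raises(self):
        img = self._image(np.ones((64, 64), complex))
        with pytest.raises(EmptyProfileError):
            extract_radial_profile(img, (0.25, 0.25), 1e-9)

    def test_center_outside_image_raises(self):
        img = self._image(np.ones((16, 16), complex))
        with pytest.raises(InvalidInputError):
            extract_radial_profile(img, (100.0, 2.0), 1e-3)


class TestEstimateCenter:
    def test_zero_image_falls_back_to_centre(self):
        assert estimate_center(np.zeros((65, 65))) == (32.0, 32.0)

    def test_symmetric_field_centre(self, midrange_params):
        acq = WaveAcquisition(frequencies=(2100.0,))
        series = synthesize_wave_series(midrange_params, acq, noise_sd=0.0, seed=0)
        h = temporal_harmonic(series.phase[2100.0])
        assert estimate_center(np.where(acq.tube_mask(), h, 0)) == (31.5, 31.5)


class TestFitBessel:
    def _profile_from_k(self, k, snr_db=None, rng=None):
        r = np.linspace(1e-4, 3.5e-3, 120)
        u = j0_complex(k * r)
        if snr_db is not None:
            sd = float(np.sqrt(np.mean(np.abs(u) ** 2))) / 10 ** (snr_db / 20.0)
            u = u + sd / math.sqrt(2.0) * (rng.standard_normal(r.size)
                                           + 1j * rng.standard_normal(r.size))
        return RadialProfile(r=r, u=u, n_px=np.ones(r.size, int))

    def test_noiseless_recovery_within_0p1pct(self):
        f = 2100.0
        omega = 2 * math.pi * f
        k_true = complex(omega / 2.5, -omega / (2 * math.pi * 1.0))
        _, k, resid = fit_bessel(self._profile_from_k(k_true), f)
        assert abs(k.real - k_true.real) / k_true.real < 1e-3
        assert abs(k.imag - k_true.imag) / abs(k_true.imag) < 1e-3
        assert resid < 1e-6

    def test_flat_profile_flags_failure(self):
        prof = RadialProfile(r=np.linspace(1e-4, 3e-3, 50),
                             u=np.full(50, 1.0 + 0.5j),
                             n_px=np.ones(50, int))
        _, _, resid = fit_bessel(prof, 2100.0)
        assert math.isinf(resid)

    def test_too_few_points_raises(self):
        prof = RadialProfile(r=np.linspace(1e-4, 3e-3, 5),
                             u=np.ones(5, complex), n_px=np.ones(5, int))
        with pytest.raises(InvalidInputError):
            fit_bessel(prof, 2100.0)

    def test_noisy_recovery_20_seeds(self):
        """SNR 30 dB on the profile: median k' error < 2%."""
        f = 2100.0
        omega = 2 * math.pi * f
        k_true = complex(omega / 2.5, -omega / (2 * math.pi * 1.0))
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            prof = self._profile_from_k(k_true, snr_db=30.0, rng=rng)
            _, k, _ = fit_bessel(prof, f)
            errs.append(abs(k.real - k_true.real) / k_true.real)
        assert np.median(errs) < 0.02


class TestValidateFrequency:
    def _point(self, c, f):
        omega = 2 * math.pi * f
        return DispersionPoint(f=f, k_re=omega / c, k_im=-100.0, c=c,
                               a=1.0)

    def test_short_wavelength_retained(self):
        pt = validate_frequency(self._point(3.0, 1300.0), 7e-3)
        assert pt.valid and pt.reason == "none"

    def test_long_wavelength_excluded(self):
        pt = validate_frequency(self._point(10.0, 500.0), 7e-3)
        assert not pt.valid and pt.reason == "wavelength"

    def test_boundary_exactly_two_diameters_retained(self):
        # lambda == 2d: the rule is strict "exceeding", so the point stays
        pt = validate_frequency(self._point(14e-3 * 500.0, 500.0), 7e-3)
        assert pt.valid

    def test_overshoot_propagates(self):
        pt = validate_frequency(self._point(3.0, 1300.0), 7e-3, overshoot=True)
        assert not pt.valid and pt.reason == "overshoot"

    def test_exclusion_monotone_in_c(self):
        """Raising c at fixed f lengthens the wavelength, so validity flips
        at most once, from valid to excluded."""
        f, d = 500.0, 7e-3
        cs = np.linspace(0.5, 20.0, 100)
        valid = [validate_frequency(self._point(c, f), d).valid for c in cs]
        # once invalid (c too high -> lambda too long), it stays invalid
        first_invalid = valid.index(False) if False in valid else len(valid)
        assert all(valid[:first_invalid])
        assert not any(valid[first_invalid:])


class TestEndToEnd:
    def test_noiseless_round_trip_within_1pct(self, band_acq):
        """synthesize -> unwrap -> harmonic -> profile -> fit recovers the
        spring-pot dispersion at every retained frequency."""
        p = SpringpotParams(mu=2000.0, alpha=0.5)
        series = synthesize_wave_series(p, band_acq, noise_sd=0.0, seed=3)
        points = invert_series(series)
        assert len(points) == 11
        for pt in points:
            c0, a0 = springpot_dispersion_oracle(2000.0, 0.5, pt.f)
            assert pt.valid
            assert abs(pt.c - c0) / c0 < 0.01
            assert abs(pt.a - a0) / a0 < 0.01

    def test_dispersion_identities_hold_exactly(self, band_acq,
                                                midrange_params):
        series = synthesize_wave_series(midrange_params, band_acq,
                                        noise_sd=0.02, seed=5)
        for pt in invert_series(series):
            omega = 2 * math.pi * pt.f
            assert pt.c == pytest.approx(omega / pt.k_re, rel=1e-12)
            assert pt.a == pytest.approx(-omega / (2 * math.pi * pt.k_im),
                                         rel=1e-12)

    def test_low_frequencies_excluded_for_stiff_sample(self):
        """A stiff sample pushes the 500/900 Hz wavelengths past twice the
        tube diameter, so the rule (not a hard-coded list) excludes them."""
        acq = WaveAcquisition()
        p = SpringpotParams(mu=8.0e5, alpha=0.3)   # c ~ 12.7 m/s at 500 Hz
        series = synthesize_wave_series(p, acq, noise_sd=0.0, seed=0)
        points = {pt.f: pt for pt in invert_series(series)}
        assert not points[500.0].valid
        assert points[500.0].reason == "wavelength"
        assert not points[900.0].valid
        assert points[5300.0].valid
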