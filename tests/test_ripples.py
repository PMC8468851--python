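"""Ripple wavelength: radial spectrum, smoothing, peak selection."""

import math

import numpy as np
import pytest

from myxovision import ripples, synthetic
from myxovision.core import Image
from myxovision.ripples import SpectrumProfile
from myxovision.synthetic import RippleSceneParams


def plane_wave(n: int, k: int, phi: float = 0.0, amp: float = 1.0) -> np.ndarray:
    """Exactly k periods across an n-pixel field at orientation phi."""
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    coord = cc * np.cos(phi) + rr * np.sin(phi)
    return amp * np.sin(2 * np.pi * k * coord / n)


class TestRadialSpectrum:
    def test_constant_image_has_zero_power_above_dc(self):
        prof = ripples.radial_spectrum(np.full((64, 64), 0.8))
        assert np.allclose(prof.amplitude[1:], 0.0, atol=1e-9)
        assert prof.amplitude[0] > 0  # DC bin carries the mean

    def test_single_plane_wave_dominates_its_bin(self):
        n, k = 128, 10
        prof = ripples.radial_spectrum(plane_wave(n, k))
        others = np.delete(prof.amplitude[1:], k - 1)
        assert prof.amplitude[k] > 10 * others.max()

    def test_superposition_keeps_each_component_bin_value(self):
        """Waves occupying disjoint bins: the radial profile of the sum
        equals each wave's own profile at its bin (DFT linearity)."""
        n = 128
        a = plane_wave(n, 8, amp=1.0)
        b = plane_wave(n, 20, phi=np.pi / 2, amp=0.5)
        prof_a = ripples.radial_spectrum(a)
        prof_b = ripples.radial_spectrum(b)
        prof = ripples.radial_spectrum(a + b)
        assert prof.amplitude[8] == pytest.approx(prof_a.amplitude[8], rel=1e-9)
        assert prof.amplitude[20] == pytest.approx(prof_b.amplitude[20], rel=1e-9)
        assert prof.amplitude[8] > 0 and prof.amplitude[20] > 0

    def test_profile_length_is_half_side_plus_one(self):
        prof = ripples.radial_spectrum(np.zeros((100, 100)))
        assert prof.k[-1] == 50
        assert len(prof.amplitude) == 51

    def test_non_square_input_center_cropped_with_warning(self):
        img = np.zeros((64, 100))
        img += plane_wave(100, 10)[:64, :]
        with pytest.warns(UserWarning):
            prof = ripples.radial_spectrum(img)
        assert prof.k[-1] == 32

    def test_tiny_image_rejected(self):
        with pytest.raises(ValueError):
            ripples.radial_spectrum(np.zeros((4, 4)))


class TestSmooth:
    def test_interior_impulse(self):
        out = ripples.smooth(np.array([0.0, 0.0, 9.0, 0.0, 0.0]))
        assert np.allclose(out, [0.0, 3.0, 3.0, 3.0, 0.0])

    def test_endpoints_use_two_neighbors(self):
        out = ripples.smooth(np.array([6.0, 0.0, 0.0, 0.0, 2.0]))
        assert out[0] == 3.0   # (6+0)/2
        assert out[-1] == 1.0  # (0+2)/2

    def test_linear_ramp_fixed_in_interior(self):
        ramp = np.arange(10, dtype=float)
        out = ripples.smooth(ramp)
        assert np.allclose(out[1:-1], ramp[1:-1])

    def test_constant_profile_unchanged(self):
        out = ripples.smooth(np.full(8, 2.5))
        assert np.allclose(out, 2.5)

    def test_short_profile_returned_unchanged_with_warning(self):
        with pytest.warns(UserWarning):
            out = ripples.smooth(np.array([1.0, 2.0]))
        assert np.allclose(out, [1.0, 2.0])


class TestDetectWavelength:
    def test_default_cutoff_from_84_micron_limit(self):
        assert ripples.default_kmin(504.0) == 6
        assert ripples.default_kmin(84.0) == 1
        assert ripples.default_kmin(85.0) == 2

    def test_known_example_24_periods_over_504_gives_21(self):
        img = Image(plane_wave(504, 24) * 0.5 + 0.5, pixel_size_um=1.0)
        res = ripples.estimate_wavelength(img)
        assert res.k1 == 24
        assert res.lambda_um == pytest.approx(21.0)
        assert res.kmin == 6

    def test_known_example_11_periods_over_504_gives_about_46(self):
        img = Image(plane_wave(504, 11) * 0.5 + 0.5, pixel_size_um=1.0)
        res = ripples.estimate_wavelength(img)
        assert res.k1 == 11
        assert round(res.lambda_um) == 46

    def test_low_frequency_gradient_rejected_by_cutoff(self):
        """Power only below kmin (a large-scale gradient plus a weak ripple):
        the cutoff must skip the dominant low-k peak."""
        n = 504
        img = plane_wave(n, 2, amp=5.0) + plane_wave(n, 24, amp=0.5)
        res = ripples.estimate_wavelength(Image(img, pixel_size_um=1.0))
        assert res.k0 < res.kmin    # the global peak the cutoff rejects
        assert res.k1 == 24
        assert res.lambda_um == pytest.approx(21.0)

    def test_no_power_above_cutoff_gives_no_ripple_sentinel(self):
        prof = SpectrumProfile(
            k=np.arange(11),
            amplitude=np.r_[5.0, np.zeros(10)],
            amplitude_smoothed=None,
        )
        prof = ripples.smooth_profile(prof)
        res = ripples.detect_wavelength(prof, L_um=100.0, kmin=3)
        assert res.k1 is None and res.lambda_um is None

    def test_rotation_invariant_within_one_bin(self):
        base = None
        for phi in (0.0, 0.4, np.pi / 2, 1.1):
            img = Image(plane_wave(504, 24, phi=phi) * 0.5 + 0.5)
            res = ripples.estimate_wavelength(img)
            if base is None:
                base = res.k1
            assert abs(res.k1 - base) <= 1

    def test_pixel_size_scales_wavelength_not_wave_number(self):
        img1 = Image(plane_wave(252, 12) * 0.5 + 0.5, pixel_size_um=1.0)
        img2 = Image(plane_wave(252, 12) * 0.5 + 0.5, pixel_size_um=2.0)
        r1 = ripples.estimate_wavelength(img1)
        r2 = ripples.estimate_wavelength(img2)
        assert r1.k1 == r2.k1 == 12
        assert r2.lambda_um == pytest.approx(2 * r1.lambda_um)

    @pytest.mark.parametrize("lam", [20.0, 30.0, 40.0, 50.0, 60.0, 80.0])
    def test_recovery_over_wavelength_range(self, lam):
        """Generated λ snaps to the nearest integer period count; the
        estimator must return exactly L / round(L/λ)."""
        L = 504.0
        p = RippleSceneParams(
            field_size_px=504, wavelength_um=lam, noise_sigma=0.02, seed=3
        )
        _, fluor, _ = synthetic.generate_ripple_scene(p)
        res = ripples.estimate_wavelength(fluor)
        assert res.k1 == round(L / lam)
        assert res.lambda_um == pytest.approx(L / round(L / lam))

    def test_first_local_peak_mode_prefers_lower_k_of_two_ridges(self):
        amp = np.zeros(51)
        amp[12] = 4.0   # weaker low-k ridge
        amp[30] = 10.0  # dominant high-k ridge
        prof = ripples.smooth_profile(
            SpectrumProfile(k=np.arange(51), amplitude=amp,
                            amplitude_smoothed=None)
        )
        glob = ripples.detect_wavelength(prof, L_um=504.0, kmin=6, peak="global")
        first = ripples.detect_wavelength(prof, L_um=504.0, kmin=6,
                                          peak="first-local")
        assert glob.k1 == 30
        assert first.k1 == 12

    def test_invalid_kmin_rejected(self):
        prof = ripples.radial_spectrum(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            ripples.detect_wavelength(prof, L_um=16.0, kmin=0)


class TestTimeseries:
    def test_constant_wavelength_movie(self):
        p = RippleSceneParams(field_size_px=168, wavelength_um=21.0, seed=0)
        frames = []
        for s in range(3):
            q = RippleSceneParams(field_size_px=168, wavelength_um=21.0, seed=s)
            frames.append(synthetic.generate_ripple_scene(q)[1])
        df = ripples.wavelength_timeseries(frames)
        assert list(df["frame"]) == [0, 1, 2]
        assert np.allclose(df["lambda_um"], 21.0)

    def test_step_change_in_wavelength_tracked(self):
        frames = [
            synthetic.generate_ripple_scene(
                RippleSceneParams(field_size_px=252, wavelength_um=lam, seed=1)
            )[1]
            for lam in (21.0, 21.0, 42.0, 42.0)
        ]
        df = ripples.wavelength_timeseries(frames)
        assert list(df["k1"]) == [12, 12, 6, 6]

    def test_rippleless_frame_reports_nan(self):
        flat = Image(np.full((128, 128), 0.5))
        df = ripples.wavelength_timeseries([flat])
        assert math.isnan(df.loc[0, "lambda_um"])

    def test_mixed_shapes_rejected(self):
        with pytest.raises(ValueError):
            ripples.wavelength_timeseries(
                [Image(np.zeros((16, 16))), Image(np.zeros((17, 17)))]
            )
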