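"""Attenuation correction, unmixing and concentration calibration."""

import numpy as np
import pytest

from sfdiq import forward
from sfdiq.fluorescence import (
    BasisSpectra,
    CalibrationCurve,
    CorrectionFactorMap,
    FluorescenceImage,
    correct_fluorescence,
    correction_factor,
    fit_calibration,
    synthetic_basis_spectra,
    to_concentration,
    unmix_spectra,
)
from sfdiq.inversion import PropertyMap
from sfdiq.scene import simulate_fluorescence

from conftest import homogeneous_scene


def prop_map(mua, musp, wavelength, shape=(8, 8)):
    return PropertyMap(
        mua_map=np.full(shape, float(mua)),
        musp_map=np.full(shape, float(musp)),
        wavelength=wavelength,
    )


class TestCorrectionFactor:
    def test_value_matches_hand_evaluation(self):
        cf = correction_factor(prop_map(1.0, 20.0, 660.0), prop_map(0.6, 18.0, 740.0))
        assert np.allclose(cf.x1d, 0.007915302394079607)

    def test_doubling_excitation_absorption_decreases_x1d(self):
        base = correction_factor(prop_map(1.0, 20.0, 660.0), prop_map(0.6, 18.0, 740.0))
        high = correction_factor(prop_map(2.0, 20.0, 660.0), prop_map(0.6, 18.0, 740.0))
        assert np.all(high.x1d < base.x1d)

    def test_union_mask_propagates(self):
        pm_ex = prop_map(1.0, 20.0, 660.0)
        pm_em = prop_map(0.6, 18.0, 740.0)
        pm_ex.mask[0, 0] = False
        pm_em.mask[1, 1] = False
        cf = correction_factor(pm_ex, pm_em)
        assert not cf.mask[0, 0] and not cf.mask[1, 1]
        assert np.isnan(cf.x1d[0, 0])


class TestCorrectFluorescence:
    def test_identity_correction(self):
        f = FluorescenceImage(f=np.full((4, 4), 7.0), ex_wavelength=660.0,
                              em_wavelength=740.0)
        cf = CorrectionFactorMap(x1d=np.ones((4, 4)), ex_wavelength=660.0,
                                 em_wavelength=740.0)
        out = correct_fluorescence(f, cf, background=0.0)
        np.testing.assert_array_equal(out.f, f.f)
        assert out.background_subtracted

    def test_generator_round_trip_is_exact(self):
        """Noise-free simulate -> correct recovers gain * concentration."""
        scene = homogeneous_scene(
            0.8, 15.0, concentrations={"pop": 2.5}, fluorescence_gain=1e4
        )
        raw = simulate_fluorescence(scene, 490.0, 590.0)
        f_raw = FluorescenceImage(f=raw, ex_wavelength=490.0, em_wavelength=590.0)
        cf = correction_factor(
            prop_map(0.8, 15.0, 490.0, shape=scene.shape),
            prop_map(0.8, 15.0, 590.0, shape=scene.shape),
        )
        out = correct_fluorescence(f_raw, cf)
        np.testing.assert_allclose(out.f, 1e4 * 2.5, rtol=1e-6)

    def test_background_exceeding_signal_warns_and_zeroes(self):
        f = FluorescenceImage(f=np.full((4, 4), 5.0), ex_wavelength=660.0,
                              em_wavelength=740.0)
        cf = CorrectionFactorMap(x1d=np.ones((4, 4)), ex_wavelength=660.0,
                                 em_wavelength=740.0)
        with pytest.warns(UserWarning, match="background"):
            out = correct_fluorescence(f, cf, background=10.0)
        assert np.all(out.f == 0.0)

    def test_shape_mismatch_raises(self):
        f = FluorescenceImage(f=np.ones((4, 4)), ex_wavelength=660.0, em_wavelength=740.0)
        cf = CorrectionFactorMap(x1d=np.ones((5, 5)), ex_wavelength=660.0,
                                 em_wavelength=740.0)
        with pytest.raises(ValueError, match="shape"):
            correct_fluorescence(f, cf)


class TestUnmixing:
    def test_identity_basis_returns_channel_values(self):
        basis = BasisSpectra(channels=np.array([590.0, 650.0, 720.0]),
                             spectra={"a": [1, 0, 0], "b": [0, 1, 0], "c": [0, 0, 1]})
        imgs = [np.full((3, 3), v) for v in (2.0, 5.0, 9.0)]
        amps, resid = unmix_spectra(imgs, basis)
        assert np.allclose(amps["a"], 2.0)
        assert np.allclose(amps["b"], 5.0)
        assert np.allclose(amps["c"], 9.0)
        assert np.allclose(resid, 0.0)

    def test_constructed_mixture_recovered(self):
        basis = synthetic_basis_spectra([560.0, 590.0, 620.0, 680.0, 720.0])
        a = basis.matrix()
        names = basis.names
        true_amp = {"auto": 0.6, "dox": 0.4, "pop": 0.0}
        mix = a @ np.array([true_amp[n] for n in names])
        imgs = [np.full((2, 2), v) for v in mix]
        amps, resid = unmix_spectra(imgs, basis)
        for name in names:
            assert np.allclose(amps[name], true_amp[name], atol=1e-8)
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_noise_pixels_stay_nonnegative(self, rng):
        basis = synthetic_basis_spectra([560.0, 590.0, 620.0, 680.0, 720.0])
        imgs = [rng.normal(0, 1, (4, 4)) for _ in basis.channels]
        amps, _ = unmix_spectra(imgs, basis)
        for img in amps.values():
            assert np.all(img >= 0)

    def test_rank_deficient_basis_raises(self):
        basis = BasisSpectra(channels=np.array([590.0, 650.0, 720.0]),
                             spectra={"a": [1, 1, 0], "b": [2, 2, 0]})
        with pytest.raises(ValueError, match="dependent"):
            unmix_spectra([np.ones((2, 2))] * 3, basis)


class TestCalibration:
    def test_exact_line(self):
        curve = fit_calibration([2, 4, 6, 8], [6, 12, 18, 24])
        assert curve.slope == pytest.approx(3.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.concentration_range == (2.0, 8.0)

    def test_noisy_line_slope_within_interval(self, rng):
        c = np.repeat([2.0, 4.0, 6.0, 8.0], 10)
        f = 3.0 * c + rng.normal(0, 0.5, c.size)
        curve = fit_calibration(c, f)
        # standard error of the slope for this design is ~0.025; allow 4 sigma
        assert curve.slope == pytest.approx(3.0, abs=0.15)
        assert curve.r_squared > 0.98

    def test_single_point_raises(self):
        with pytest.raises(ValueError, match="two distinct"):
            fit_calibration([4.0], [12.0])
        with pytest.raises(ValueError, match="two distinct"):
            fit_calibration([4.0, 4.0], [12.0, 12.1])

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            fit_calibration([2, 4, 6, 8], [24, 18, 12, 6])


class TestToConcentration:
    def _curve(self, slope=1e4, intercept=0.0):
        return CalibrationCurve(slope=slope, intercept=intercept, r_squared=1.0,
                                concentration_range=(0.0, 10.0))

    def test_intercept_maps_to_zero(self):
        f = FluorescenceImage(f=np.full((3, 3), 50.0), ex_wavelength=490.0,
                              em_wavelength=590.0)
        cm = to_concentration(f, self._curve(slope=10.0, intercept=50.0))
        assert np.all(cm.c == 0.0)

    def test_round_trip_with_generator_gain(self):
        scene = homogeneous_scene(
            0.8, 15.0, concentrations={"dox": 4.0}, fluorescence_gain=1e4
        )
        raw = simulate_fluorescence(scene, 490.0, 590.0)
        f_raw = FluorescenceImage(f=raw, ex_wavelength=490.0, em_wavelength=590.0)
        cf = correction_factor(
            prop_map(0.8, 15.0, 490.0, shape=scene.shape),
            prop_map(0.8, 15.0, 590.0, shape=scene.shape),
        )
        f_corr = correct_fluorescence(f_raw, cf)
        cm = to_concentration(f_corr, self._curve(slope=1e4))
        np.testing.assert_allclose(cm.c, 4.0, rtol=1e-6)

    def test_below_intercept_clipped_and_counted(self):
        f = FluorescenceImage(f=np.array([[0.0, 100.0]]), ex_wavelength=490.0,
                              em_wavelength=590.0)
        cm = to_concentration(f, self._curve(slope=10.0, intercept=50.0))
        assert cm.c[0, 0] == 0.0
        assert cm.n_clipped == 1


def test_basis_spectra_csv_round_trip(tmp_path):
    basis = synthetic_basis_spectra([560.0, 590.0, 620.0, 680.0, 720.0])
    path = tmp_path / "basis.csv"
    basis.to_csv(path)
    back = BasisSpectra.from_csv(path)
    assert back.names == basis.names
    for name in basis.names:
        np.testing.assert_allclose(back.spectra[name], basis.spectra[name])
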