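"""Optical-property inversion: round trips, LUT agreement, degenerate inputs."""

import warnings

import numpy as np
import pytest

from sfdiq import forward
from sfdiq.demodulation import calibrate_stack
from sfdiq.inversion import (
    DEFAULT_BOUNDS,
    build_lut,
    fit_pixel,
    invert_map,
    lut_invert,
)
from sfdiq.scene import simulate_acquisition

from conftest import homogeneous_scene


def rd_vector(mua, musp, freqs):
    return forward.diffuse_reflectance(mua, musp, np.asarray(freqs.frequencies))


class TestFitPixel:
    def test_noise_free_round_trip_within_0p1_percent(self, freqs5):
        mua, musp, rms = fit_pixel(rd_vector(0.8, 15.0, freqs5), freqs5)
        assert mua == pytest.approx(0.8, rel=1e-3)
        assert musp == pytest.approx(15.0, rel=1e-3)
        assert rms < 1e-8

    @pytest.mark.parametrize("truth", [(0.5, 10.0), (1.0, 20.0), (1.5, 30.0)])
    def test_round_trip_across_phantom_range(self, freqs5, truth):
        mua, musp, _ = fit_pixel(rd_vector(*truth, freqs5), freqs5)
        assert mua == pytest.approx(truth[0], rel=1e-3)
        assert musp == pytest.approx(truth[1], rel=1e-3)

    def test_zero_vector_is_masked(self, freqs5):
        mua, musp, rms = fit_pixel(np.zeros(5), freqs5)
        assert np.isnan(mua) and np.isnan(musp)

    def test_length_mismatch_raises(self, freqs5):
        with pytest.raises(ValueError, match="frequencies"):
            fit_pixel(np.ones(4), freqs5)


class TestLUT:
    def test_exact_table_hit_returns_node(self, freqs5):
        lut = build_lut(freqs5.frequencies, n_mua=11, n_musp=11)
        i, j = 5, 5
        vec = lut.rd_table[i, j]
        mua, musp = lut_invert(lut, vec)
        assert mua == pytest.approx(lut.mua_grid[i], abs=1e-6)
        assert musp == pytest.approx(lut.musp_grid[j], abs=1e-6)

    def test_lut_agrees_with_full_fit_within_2_percent(self, freqs5, rng):
        lut = build_lut(freqs5.frequencies)
        for _ in range(20):
            mua_t = rng.uniform(0.5, 1.5)
            musp_t = rng.uniform(10.0, 30.0)
            vec = rd_vector(mua_t, musp_t, freqs5)
            mua_l, musp_l = lut_invert(lut, vec)
            mua_f, musp_f, _ = fit_pixel(vec, freqs5)
            assert mua_l == pytest.approx(mua_f, rel=0.02)
            assert musp_l == pytest.approx(musp_f, rel=0.02)

    def test_out_of_hull_vector_clamped_with_warning(self, freqs5):
        lut = build_lut(freqs5.frequencies)
        # brighter than the lowest-absorption curve in the table
        vec = rd_vector(0.05, 20.0, freqs5)
        with pytest.warns(UserWarning, match="hull"):
            mua, musp = lut_invert(lut, vec)
        assert mua == pytest.approx(lut.mua_grid[0])

    def test_table_monotone_over_tissue_range(self, freqs5):
        """Within the tissue range (musp >= 10 cm^-1) the table is strictly
        monotone along each parameter axis; at very low scattering and high
        frequency the diffusion form loses strict monotonicity in mua."""
        lut = build_lut(freqs5.frequencies, mua_range=(0.3, 2.0),
                        musp_range=(10.0, 40.0))
        assert np.all(np.diff(lut.rd_table, axis=0) < 0)
        assert np.all(np.diff(lut.rd_table, axis=1) > 0)


def test_two_frequency_identifiability_by_brute_force(freqs5):
    """(mua, musp) -> (Rd(f_low), Rd(f_high)) is injective over the phantom range."""
    f_low, f_high = 0.0, 2.0
    mua = np.linspace(0.5, 1.5, 30)
    musp = np.linspace(10, 30, 30)
    rd_lo = forward.diffuse_reflectance(mua[:, None], musp[None, :], f_low)
    rd_hi = forward.diffuse_reflectance(mua[:, None], musp[None, :], f_high)
    pts = np.column_stack([rd_lo.ravel(), rd_hi.ravel()])
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    assert d2.min() > 1e-12


class TestInvertMap:
    def test_homogeneous_noise_free_recovery(self, freqs5, ref_phantom):
        scene = homogeneous_scene(0.8, 15.0)
        stack = simulate_acquisition(scene, freqs5, [490.0, 590.0])
        dr = calibrate_stack(stack, ref_phantom)
        pm = invert_map(dr, 490.0)
        assert pm.mask.all()
        np.testing.assert_allclose(pm.mua_map, 0.8, rtol=1e-3)
        np.testing.assert_allclose(pm.musp_map, 15.0, rtol=1e-3)

    def test_vectorized_fit_matches_reference_fit(self, freqs5, ref_phantom):
        """The batched Levenberg-Marquardt route and scipy least_squares agree."""
        scene = homogeneous_scene(1.2, 25.0, noise={"mult_sd": 0.01}, seed=11)
        stack = simulate_acquisition(scene, freqs5, [490.0, 590.0])
        dr = calibrate_stack(stack, ref_phantom)
        pm = invert_map(dr, 490.0)
        cube, fxs = dr.rd_cube(490.0)
        for (r, c) in [(0, 0), (5, 7), (31, 31)]:
            mua_ref, musp_ref, _ = fit_pixel(cube[:, r, c], fxs)
            assert pm.mua_map[r, c] == pytest.approx(mua_ref, rel=1e-4)
            assert pm.musp_map[r, c] == pytest.approx(musp_ref, rel=1e-4)

    def test_missing_wavelength_raises(self, freqs5, ref_phantom):
        scene = homogeneous_scene(0.8, 15.0)
        stack = simulate_acquisition(scene, freqs5, [490.0, 590.0])
        dr = calibrate_stack(stack, ref_phantom)
        with pytest.raises(ValueError, match="660"):
            invert_map(dr, 660.0)

    def test_binning_shape_contract(self, freqs5):
        from sfdiq.scene import OpticalProperties, make_reference_phantom

        scene = homogeneous_scene(0.8, 15.0, shape=(64, 64))
        props = {wl: OpticalProperties(mua=1.0, musp=20.0, wavelength=wl)
                 for wl in (490.0, 590.0)}
        ref = make_reference_phantom(props, freqs5, shape=(64, 64), pixel_size_mm=0.5)
        stack = simulate_acquisition(scene, freqs5, [490.0, 590.0])
        dr = calibrate_stack(stack, ref)
        pm = invert_map(dr, 490.0, binning=4)
        assert pm.shape == (16, 16)
        np.testing.assert_allclose(pm.mua_map, 0.8, rtol=1e-3)

    def test_dead_pixels_masked_not_crashed(self, freqs5, ref_phantom):
        scene = homogeneous_scene(0.8, 15.0)
        stack = simulate_acquisition(scene, freqs5, [490.0, 590.0])
        dr = calibrate_stack(stack, ref_phantom)
        for fx in freqs5.frequencies:
            dr.rd[(490.0, fx)][3, 3] = 0.0  # dead pixel at every frequency
        pm = invert_map(dr, 490.0)
        assert not pm.mask[3, 3]
        assert np.isnan(pm.mua_map[3, 3])
        assert pm.mask.sum() == pm.mask.size - 1

    def test_bias_shrinks_as_noise_shrinks(self, freqs5, ref_phantom):
        """Mean |error| in mua decreases monotonically over three noise levels."""
        errors = []
        for sd in (0.04, 0.01, 0.0):
            scene = homogeneous_scene(1.0, 20.0, noise={"mult_sd": sd} if sd else {},
                                      seed=21)
            stack = simulate_acquisition(scene, freqs5, [490.0, 590.0])
            dr = calibrate_stack(stack, ref_phantom)
            pm = invert_map(dr, 490.0)
            errors.append(np.nanmean(np.abs(pm.mua_map - 1.0)))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-3


def test_property_map_hdf5_round_trip(tmp_path, freqs5, ref_phantom):
    scene = homogeneous_scene(0.8, 15.0)
    stack = simulate_acquisition(scene, freqs5, [490.0, 590.0])
    pm = invert_map(calibrate_stack(stack, ref_phantom), 490.0)
    path = tmp_path / "props.h5"
    pm.to_hdf5(path)
    back = pm.from_hdf5(path)
    np.testing.assert_array_equal(back.mua_map, pm.mua_map)
    assert back.wavelength == 490.0
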