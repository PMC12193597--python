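"""Scene rasterization, acquisition simulation, serialization."""

import numpy as np
import pytest

from sfdiq.scene import (
    OpticalProperties,
    Region,
    SceneSpec,
    SpatialFrequencySet,
    build_scene,
    laparoscopic_frequencies,
    make_reference_phantom,
    read_stack,
    simulate_acquisition,
    simulate_fluorescence,
    widefield_frequencies,
    write_stack,
)

from conftest import homogeneous_scene


def _props(mua, musp, wavelengths):
    return {
        float(w): OpticalProperties(mua=mua, musp=musp, wavelength=float(w))
        for w in wavelengths
    }


class TestFrequencySet:
    def test_default_phases_are_thirds_of_a_cycle(self, freqs5):
        assert np.allclose(freqs5.phases, (0, 2 * np.pi / 3, 4 * np.pi / 3))

    @pytest.mark.parametrize("bad", [(), (0.5, 1.0), (0.0, 1.0, 0.5)])
    def test_invalid_frequency_lists_raise(self, bad):
        with pytest.raises(ValueError):
            SpatialFrequencySet(frequencies=bad)

    def test_protocol_spans(self):
        wf = widefield_frequencies()
        lap = laparoscopic_frequencies()
        assert len(wf) == 22 and wf[0] == 0.0 and wf[-1] == pytest.approx(3.1764)
        assert len(lap) == 5 and lap[-1] == pytest.approx(2.0)


class TestBuildScene:
    def test_single_region_gives_uniform_maps(self):
        scene = homogeneous_scene(0.8, 15.0, concentrations={"pop": 2.0})
        props_maps, conc_maps = build_scene(scene)
        mua, musp = props_maps[490.0]
        assert np.all(mua == 0.8) and np.all(musp == 15.0)
        assert np.all(conc_maps["pop"] == 2.0)

    def test_tumor_inclusion_scales_masked_pixels(self):
        wls = (660.0,)
        bg = Region("periphery", {"type": "full"}, props=_props(0.7, 17.0, wls))
        tumor = Region(
            "tumor",
            {"type": "ellipse", "center": [16, 16], "axes": [6, 8]},
            props=_props(0.7 * 1.4, 17.0 * 1.15, wls),
        )
        scene = SceneSpec(shape=(32, 32), pixel_size_mm=0.5, regions=[bg, tumor])
        props_maps, _ = build_scene(scene)
        mua, musp = props_maps[660.0]
        inside = mua == pytest.approx(0.98)
        assert mua[16, 16] == pytest.approx(0.98)
        assert musp[16, 16] == pytest.approx(17.0 * 1.15)
        assert mua[0, 0] == pytest.approx(0.7)
        assert 0 < np.sum(np.isclose(mua, 0.98)) < mua.size

    def test_later_region_wins_on_overlap(self):
        wls = (490.0,)
        r1 = Region("a", {"type": "full"}, props=_props(0.5, 10.0, wls))
        r2 = Region("b", {"type": "ellipse", "center": [8, 8], "axes": [4, 4]},
                    props=_props(1.5, 30.0, wls))
        r3 = Region("c", {"type": "ellipse", "center": [8, 8], "axes": [2, 2]},
                    props=_props(1.0, 20.0, wls))
        scene = SceneSpec(shape=(16, 16), pixel_size_mm=0.5, regions=[r1, r2, r3])
        props_maps, _ = build_scene(scene)
        mua, _ = props_maps[490.0]
        assert mua[8, 8] == 1.0  # innermost (last) region wins
        assert mua[8, 5] == 1.5
        assert mua[0, 0] == 0.5

    def test_missing_wavelength_raises(self):
        r1 = Region("a", {"type": "full"}, props=_props(0.5, 10.0, (490.0,)))
        scene = SceneSpec(shape=(8, 8), pixel_size_mm=0.5, regions=[r1])
        with pytest.raises(ValueError, match="590"):
            build_scene(scene, wavelengths=[590.0])

    def test_uncovered_pixels_raise(self):
        r1 = Region("a", {"type": "ellipse", "center": [4, 4], "axes": [2, 2]},
                    props=_props(0.5, 10.0, (490.0,)))
        scene = SceneSpec(shape=(8, 8), pixel_size_mm=0.5, regions=[r1])
        with pytest.raises(ValueError, match="cover"):
            build_scene(scene)


class TestSimulateAcquisition:
    def test_laparoscopic_count_is_15_per_wavelength(self, freqs5):
        scene = homogeneous_scene(0.8, 15.0, wavelengths=(490.0,), shape=(16, 16))
        stack = simulate_acquisition(scene, freqs5, [490.0], protocol_tag="laparoscopic")
        assert len(stack) == 15  # 3 phases x 5 frequencies

    def test_widefield_count_is_264(self):
        freqs = SpatialFrequencySet(frequencies=tuple(widefield_frequencies()))
        wls = (590.0, 625.0, 660.0, 740.0)
        scene = homogeneous_scene(0.8, 15.0, wavelengths=wls, shape=(8, 8))
        stack = simulate_acquisition(scene, freqs, wls)
        assert len(stack) == 264  # 3 x 22 x 4

    def test_intensities_nonnegative_with_noise(self, freqs5):
        scene = homogeneous_scene(
            0.8, 15.0, noise={"shot_scale": 5.0, "read_sd": 20.0, "mult_sd": 0.05},
            seed=7, shape=(16, 16),
        )
        stack = simulate_acquisition(scene, freqs5, [490.0, 590.0])
        assert all(np.all(img >= 0) for img in stack.images.values())

    def test_seed_determinism_is_bit_identical(self, freqs5):
        kwargs = dict(noise={"shot_scale": 2.0, "read_sd": 5.0}, seed=3, shape=(16, 16))
        s1 = simulate_acquisition(homogeneous_scene(0.8, 15.0, **kwargs), freqs5, [490.0])
        s2 = simulate_acquisition(homogeneous_scene(0.8, 15.0, **kwargs), freqs5, [490.0])
        for key in s1.images:
            np.testing.assert_array_equal(s1.images[key], s2.images[key])

    def test_bad_pixel_size_raises(self):
        regions = homogeneous_scene(0.8, 15.0).regions
        with pytest.raises(ValueError, match="pixel_size"):
            SceneSpec(shape=(8, 8), pixel_size_mm=0.0, regions=regions)


class TestSimulateFluorescence:
    def test_zero_concentration_gives_zero_image(self):
        scene = homogeneous_scene(0.8, 15.0, concentrations={"pop": 0.0})
        img = simulate_fluorescence(scene, 490.0, 590.0)
        assert np.all(img == 0.0)

    def test_homogeneous_scene_gives_constant_image(self):
        scene = homogeneous_scene(
            0.8, 15.0, concentrations={"pop": 2.0},
            fluorescence_gain=1e4, autofluorescence_level=30.0,
        )
        img = simulate_fluorescence(scene, 490.0, 590.0)
        assert np.ptp(img) == pytest.approx(0.0, abs=1e-9)
        from sfdiq import forward

        expected = 1e4 * 2.0 * forward.effective_pathlength(0.8, 15.0, 0.8, 15.0) + 30.0
        assert img[0, 0] == pytest.approx(expected)

    def test_missing_properties_raise(self):
        scene = homogeneous_scene(0.8, 15.0, concentrations={"pop": 1.0})
        with pytest.raises(ValueError, match="656"):
            simulate_fluorescence(scene, 490.0, 656.0)


class TestReferencePhantom:
    def test_two_wavelengths_present(self, freqs5):
        props = _props(1.0, 20.0, (490.0, 590.0))
        ref = make_reference_phantom(props, freqs5, shape=(8, 8))
        assert ref.stack.wavelengths == (490.0, 590.0)

    def test_empty_frequency_list_raises(self):
        with pytest.raises(ValueError):
            SpatialFrequencySet(frequencies=())


class TestSerialization:
    def test_stack_tiff_round_trip(self, tmp_path, freqs5):
        scene = homogeneous_scene(0.8, 15.0, shape=(8, 8), seed=5,
                                  noise={"read_sd": 3.0})
        stack = simulate_acquisition(scene, freqs5, [490.0, 590.0],
                                     protocol_tag="laparoscopic")
        tiff, manifest = write_stack(stack, tmp_path / "stack.tiff")
        back = read_stack(tiff, manifest)
        assert back.wavelengths == stack.wavelengths
        assert back.protocol_tag == "laparoscopic"
        assert back.binning == stack.binning
        for key in stack.images:
            np.testing.assert_allclose(back.images[key], stack.images[key], rtol=1e-6)

    def test_manifest_page_mismatch_raises(self, tmp_path, freqs5):
        import json

        scene = homogeneous_scene(0.8, 15.0, shape=(8, 8))
        stack = simulate_acquisition(scene, freqs5, [490.0])
        tiff, manifest = write_stack(stack, tmp_path / "stack.tiff")
        doc = json.loads(manifest.read_text())
        doc["wavelengths"] = [490.0, 590.0]  # promises 2 wavelengths, pages for 1
        manifest.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="pages"):
            read_stack(tiff, manifest)

    def test_scene_yaml_round_trip(self, tmp_path):
        scene = homogeneous_scene(
            0.8, 15.0, concentrations={"pop": 2.0}, seed=9,
            noise={"mult_sd": 0.01}, fluorescence_gain=5e4,
        )
        path = tmp_path / "scene.yaml"
        scene.to_yaml(path)
        back = SceneSpec.from_yaml(path)
        assert back.shape == scene.shape
        assert back.seed == scene.seed
        assert back.noise == scene.noise
        assert back.regions[0].props[490.0].mua == 0.8
        assert back.regions[0].concentrations == {"pop": 2.0}
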