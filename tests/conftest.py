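import numpy as np
import pytest

from sfdiq.scene import (
    OpticalProperties,
    Region,
    SceneSpec,
    SpatialFrequencySet,
    laparoscopic_frequencies,
    make_reference_phantom,
)


@pytest.fixture(scope="session")
def freqs5() -> SpatialFrequencySet:
    """Laparoscopic frequency set: five frequencies, 0 to 2.0 cm^-1."""
    return SpatialFrequencySet(frequencies=tuple(laparoscopic_frequencies()))


@pytest.fixture(scope="session")
def ref_phantom(freqs5):
    """Noise-free 32x32 reference phantom (mua=1.0, musp=20) at 490/590 nm."""
    props = {
        wl: OpticalProperties(mua=1.0, musp=20.0, wavelength=wl)
        for wl in (490.0, 590.0)
    }
    return make_reference_phantom(props, freqs5, shape=(32, 32), pixel_size_mm=0.5)


def homogeneous_scene(mua, musp, wavelengths=(490.0, 590.0), shape=(32, 32),
                      noise=None, seed=0, **kwargs):
    props = {
        float(wl): OpticalProperties(mua=mua, musp=musp, wavelength=float(wl))
        for wl in wavelengths
    }
    region = Region(label="bg", geometry={"type": "full"}, props=props,
                    concentrations=kwargs.pop("concentrations", {}))
    return SceneSpec(shape=shape, pixel_size_mm=0.5, regions=[region],
                     noise=noise or {}, seed=seed, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
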