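# sfdiq

Quantitative fluorescence imaging from spatial frequency domain imaging
(SFDI), for optics researchers working on image-guided photodynamic
therapy and light-triggered drug delivery.

Raw fluorescence from tissue is a biased readout of fluorophore abundance:
absorption and scattering at the excitation and emission wavelengths
attenuate the signal, to the point that a drug-rich but strongly absorbing
tumor can *look dimmer* than its surroundings. SFDI fixes this by
measuring the tissue optics first. Sinusoidal patterns at spatial
frequencies fx are projected in three phases; demodulation

    M_AC = (√2/3) √[(I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²]

and calibration against a reference phantom yield the diffuse reflectance
Rd(fx) per pixel, whose frequency dependence is inverted with a diffusion
forward model to per-pixel maps of µa and µs′ (cm⁻¹). Those maps give the
effective path length

    X_1D(ex, em) = k_ex k_em / (µeff,ex + µeff,em),   µeff = √(3 µa (µa+µs′))

and the corrected fluorescence F_corr = (F_raw − background)/X_1D is
converted to absolute concentration (µg/mL) through a linear calibration
curve. Downstream analysis covers ROI statistics, tumor/periphery contrast
ratios, photobleaching percent change, and drug-release kinetics with
plateau detection.

A synthetic scene generator (same forward optics as the pipeline) stands
in for instrument data, covering homogeneous calibration phantoms, a
tumor/periphery scene, and a timed drug-release experiment, with
seed-controlled shot/read/multiplicative noise.

## Worked example

```python
import numpy as np
from sfdiq.scene import (OpticalProperties, Region, SceneSpec,
                         SpatialFrequencySet, laparoscopic_frequencies,
                         make_reference_phantom, simulate_acquisition)
from sfdiq.demodulation import calibrate_stack
from sfdiq.inversion import invert_map

freqs = SpatialFrequencySet(frequencies=tuple(laparoscopic_frequencies()))
wls = (490.0, 590.0)
tissue = Region("tissue", {"type": "full"},
                props={w: OpticalProperties(mua=0.8, musp=15.0, wavelength=w)
                       for w in wls})
scene = SceneSpec(shape=(32, 32), pixel_size_mm=0.5, regions=[tissue],
                  noise={"mult_sd": 0.01}, seed=7)
ref = make_reference_phantom(
    {w: OpticalProperties(mua=1.0, musp=20.0, wavelength=w) for w in wls},
    freqs, shape=(32, 32), pixel_size_mm=0.5)

stack = simulate_acquisition(scene, freqs, wls, protocol_tag="laparoscopic")
dr = calibrate_stack(stack, ref)
pm = invert_map(dr, 490.0)
print(f"{len(stack)} images, recovered mua = {np.nanmean(pm.mua_map):.3f} "
      f"+/- {np.nanstd(pm.mua_map):.3f} cm^-1")
```

prints

```
30 images, recovered mua = 0.802 +/- 0.017 cm^-1
```

— 30 images because the laparoscopic protocol takes 3 phases × 5
frequencies per wavelength, and the recovered absorption matches the
scene's true 0.8 cm⁻¹ with a spread set by the 1% image noise.

The numbered drivers under `analysis/` run the three studies and write
their tables to `results/`:

- `01_phantom_accuracy.py` — property recovery over the 5×5 calibration
  phantom grid (prints mean |%err| in µa ≈ 2% at 1% image noise);
- `02_tumor_contrast.py` — tumor/periphery contrast inversion
  (raw ratio 0.98 < 1) and its restoration by correction (1.33);
- `03_release_kinetics.py` — minute-by-minute drug release rising to
  ~13 µg/mL with a plateau at 4 min, and a 53.5% photosensitizer
  photobleaching decrease.

A `sfdiq` command-line interface wraps the same library
(`sfdiq run-all --config cfg.yaml --scene scene.yaml --out dir/`, plus
`simulate`, `demod`, `invert`, `fluor`, `kinetics`).

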