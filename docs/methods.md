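# Methods

## Problem and approach

Spatial frequency domain imaging (SFDI) projects sinusoidal light patterns
of several spatial frequencies onto a tissue surface and demodulates the
reflected images. Because the frequency dependence of diffuse reflectance
separates absorption (µa) from reduced scattering (µs′), per-pixel maps of
both coefficients can be recovered and then used to correct raw
fluorescence for tissue attenuation, converting it into absolute
fluorophore concentration. `sfdiq` implements this chain — demodulation,
reference-phantom calibration, optical-property inversion,
effective-path-length fluorescence correction, concentration calibration,
and ROI/kinetics analysis — together with a synthetic forward-model scene
generator so the whole pipeline is testable without instrument data.

## Forward model

Diffuse reflectance of a homogeneous semi-infinite medium under modulated
illumination uses the standard diffusion closed form with a partial-current
boundary:

    µtr = µa + µs′,  a′ = µs′/µtr,  µeff = √(3 µa µtr)
    µeff′(fx) = √(µeff² + (2π fx)²)
    Rd(fx) = 3 A a′ / [(µeff′/µtr + 1)(µeff′/µtr + 3A)]

with `A = (1−Reff)/(2(1+Reff))` and `Reff = 0.0636 n + 0.668 + 0.710/n −
1.440/n²`, `n = 1.4`. The form satisfies `Rd(0) = 1` at zero absorption and
is accurate in the albedo range of soft-tissue phantoms. Pixel-by-pixel
instrument analyses of this kind are often driven by Monte-Carlo-generated
frequency response tables instead; the forward functions accept an
`rd_model` hook so a tabulated curve set can be substituted without
touching the rest of the pipeline. The closed form is *not* strictly
monotone in µa at very low scattering (µs′ ≈ 5 cm⁻¹) combined with high
frequency — outside the diffusion validity region — which is why the
table-monotonicity check is asserted over the tissue range (µs′ ≥ 10 cm⁻¹)
only.

## Demodulation and calibration

Three phase-shifted projections (0, 2π/3, 4π/3) per frequency give the AC
amplitude `M_AC = (√2/3)·√[(I1−I2)² + (I2−I3)² + (I3−I1)²]`, exact for a
pure sinusoid at any global phase. The planar (fx = 0) projection uses the
triplet mean instead, which shares the I0/2 scale of the AC amplitudes.
Calibration multiplies the sample/reference amplitude ratio by the model
reflectance of a phantom with known properties; this cancels source
intensity, throughput and the modulation transfer function, so no separate
flat-field step exists. Reference pixels below 1e−6 of the reference
maximum are masked to avoid division blow-up at pattern nulls.

## Inversion

Per pixel, (µa, µs′) minimizes the sum of squared differences between
measured and model Rd over all available frequencies, inside the box
µa ∈ [0.01, 5], µs′ ∈ [1, 60] cm⁻¹. A coarse 21×21 lookup table seeds the
fit to avoid local minima. Two routes solve the same objective: a
single-pixel scipy trust-region fit (`fit_pixel`, the reference path) and a
Levenberg–Marquardt iteration vectorized across all pixels of a map
(`invert_map`), with per-pixel damping, finite-difference Jacobians,
bound clipping, and convergence at relative step < 1e−11 or a damping
ceiling; a test pins the agreement of the two routes. The standalone LUT
inverse (`lut_invert`) is nearest-node search plus one table-local
Gauss–Newton step, clamped to the cell; it agrees with the full fit within
2% on noise-free interior inputs and clamps out-of-hull vectors to the
boundary with a warning. Binning averages reflectance within b×b blocks
*before* the nonlinear step, mirroring camera binning and reducing noise
where it is cheapest.

## Fluorescence correction and calibration

The correction factor is the effective path length coupling excitation
penetration and emission escape, from exponential depth profiles
`k·exp(−µeff z)` at each wavelength:

    X_1D(ex, em) = k_ex k_em / (µeff,ex + µeff,em),
    k_λ = 3 a′ A / (1 + µeff/µtr)

The build-up coefficients are pinned in one function
(`forward.fluence_buildup_factor`) so an alternative literature coefficient
set can be swapped in at a single point. X_1D is symmetric in the
(ex)↔(em) property pairs and strictly decreasing in either absorption;
µa below 0.01 cm⁻¹ is clamped so near-transparent pixels stay finite.
Corrected fluorescence is `F_corr = (F_raw − background)/X_1D`, background
being either a scalar/pre-injection frame or per-pixel nonnegative
least-squares unmixing onto basis spectra (drug, photosensitizer,
autofluorescence; unmixing needs at least as many channels as components).
A linear calibration curve fit on phantoms of known concentration
(defaults 2, 4, 6, 8 µg/mL) converts corrected signal to µg/mL; since
correction precedes calibration, one curve serves phantoms of differing
optical properties. Negative concentration estimates are clipped to zero
and counted.

The synthetic generator applies the *same* X_1D form when producing raw
fluorescence. This is deliberate: with no released raw data, the
verifiable contract is internal consistency — noise-free round trips must
recover the ground truth exactly — not agreement with a particular
instrument's light-transport kernel. Passing tests therefore demonstrate
the pipeline's correctness given the diffusion optics, not the accuracy of
diffusion theory against real tissue.

## Kinetics and statistics

ROI statistics use sample mean and sd (ddof = 1) over valid pixels;
polygon ROIs rasterize by the pixel-center even-odd rule with canonical
winding, so vertex order does not matter. Percent change uses the
convention positive = decrease (photobleaching). The release plateau is
the first timepoint from which every later step changes the ROI mean by
less than 5% relative — a threshold chosen once as the operational meaning
of "leveling off". Group comparisons use Welch's two-sample t-test on ROI
pixels; pixels are spatially correlated, so these p-values are optimistic,
and every stats report the package writes carries that caveat.

## Synthetic scenes: what they emulate and what they do not

Scenes cover the study conditions: calibration phantoms over µa 0.5–1.5,
µs′ 10–30 cm⁻¹ at two wavelengths; a tumor with absorption +40% and
scattering +15% over the periphery carrying 0.24 vs 0.18 µg/mL
photosensitizer (ratio 1.33), which reproduces the raw-fluorescence
contrast inversion and its restoration by correction; and a release
experiment with a lightly scattering inclusion (µs′ = 5 cm⁻¹ at 490 nm)
whose drug concentration follows `c(t) = 13·(1 − e^(−t/1.5 min))` sampled
every minute for 8 min (the injected 23.1 µg/mL bolus is only partially
probed, hence the lower ceiling), plus a photosensitizer photobleaching
step 1.57 → 0.73 µg/mL. Noise is multiplicative Gaussian, Poisson-like
shot, and additive read noise, all seed-controlled. Not modeled: photon
transport beyond diffusion, depth-resolved structure, surface curvature
and profilometry effects, camera PSF/vignetting, specular residuals.
Accuracy figures measured on these scenes say nothing about those effects.

## Problem sizes and defaults

The phantom-accuracy study runs 25 phantoms × 2 wavelengths at 64×64 px
with 1% multiplicative noise and the five-frequency set (0–2.0 cm⁻¹),
calibrated against the (µa = 1.0, µs′ = 20) phantom — about 200k pixel
fits, finishing in well under a minute via the vectorized route. The
contrast and release studies use 64×64 and 48×48 scenes. Fluorescence gain
defaults to 1e5 a.u. per (µg/mL·cm), putting simulated signals in a
realistic few-hundred-count range.

## Known limitations

- Wavelengths are fitted independently; no joint spectral constraint.
- The fluorescence correction assumes homogeneous optics along depth at
  each pixel; partial-volume and layered-skin effects are not represented.
- The LUT clamps rather than extrapolates outside its hull.
- Plateau detection is threshold-based and will fire late on very noisy
  series; it reports `None` rather than guessing when the series never
  quiets down.
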