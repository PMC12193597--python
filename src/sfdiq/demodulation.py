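"""Three-phase demodulation and reference-phantom calibration.

Structured illumination projects the same sinusoid three times with phase
offsets 0, 2pi/3 and 4pi/3.  The AC modulation amplitude is recovered
pixelwise from the phase triplet

    M_AC = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2)

which is exact for a pure sinusoid regardless of its global phase.  For the
planar (fx = 0) projection the mean of the three images is used instead:
AC demodulation of an unmodulated pattern returns only noise.

Calibration against a reference phantom of known optical properties
converts instrument-scale modulation amplitudes into absolute diffuse
reflectance:

    Rd_sample(fx) = (M_sample / M_ref) * Rd_model(ref props, fx)

The ratio cancels source intensity, system throughput and the modulation
transfer function, so no separate flat-field step is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import forward
from .scene import OpticalProperties, ReferencePhantom, AcquisitionStack

__all__ = [
    "demodulate_ac",
    "demodulate_dc",
    "demodulate_stack",
    "calibrate_reflectance",
    "calibrate_stack",
    "DemodulatedReflectance",
]

log = logging.getLogger(__name__)

# pixels where the reference amplitude falls below this fraction of its
# maximum are masked invalid rather than divided through
REFERENCE_FLOOR = 1e-6


def _check_triplet(i1, i2, i3) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    i1, i2, i3 = (np.asarray(a, dtype=float) for a in (i1, i2, i3))
    if not (i1.shape == i2.shape == i3.shape):
        raise ValueError(f"phase image shapes differ: {i1.shape}, {i2.shape}, {i3.shape}")
    for k, img in enumerate((i1, i2, i3), start=1):
        if img.size and np.all(np.isnan(img)):
            raise ValueError(f"phase image {k} is all-NaN")
    return i1, i2, i3


def demodulate_ac(i1, i2, i3) -> np.ndarray:
    """Modulation amplitude of a three-phase sinusoidal image triplet."""
    i1, i2, i3 = _check_triplet(i1, i2, i3)
    return (np.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )


def demodulate_dc(i1, i2, i3) -> np.ndarray:
    """Mean (planar) intensity of a three-phase triplet."""
    i1, i2, i3 = _check_triplet(i1, i2, i3)
    return (i1 + i2 + i3) / 3.0


def demodulate_stack(stack: AcquisitionStack) -> dict:
    """Demodulate every (wavelength, frequency) triplet of a stack.

    Returns a dict ``(wavelength, fx) -> amplitude image``; the fx = 0 entry
    holds the DC (mean) image so all entries share the I0/2 scale.
    """
    out = {}
    for wl in stack.wavelengths:
        for fx in stack.frequencies:
            triplet = stack.phase_images(wl, fx)
            if len(triplet) != 3:
                raise ValueError(f"expected 3 phase images at ({wl} nm, {fx} cm^-1)")
            if fx == 0.0:
                out[(wl, fx)] = demodulate_dc(*triplet)
            else:
                out[(wl, fx)] = demodulate_ac(*triplet)
    return out


def calibrate_reflectance(
    mac_sample: np.ndarray,
    mac_ref: np.ndarray,
    ref_props: OpticalProperties,
    fx: float,
    rd_model=forward.diffuse_reflectance,
):
    """Calibrate a sample amplitude image to absolute diffuse reflectance.

    Returns ``(rd, mask)``: the calibrated reflectance (NaN where invalid)
    and a boolean validity mask.  Pixels whose reference amplitude is below
    ``REFERENCE_FLOOR`` times the reference maximum are masked.
    """
    mac_sample = np.asarray(mac_sample, dtype=float)
    mac_ref = np.asarray(mac_ref, dtype=float)
    if mac_sample.shape != mac_ref.shape:
        raise ValueError("sample and reference amplitude shapes differ")
    rd_ref = rd_model(ref_props.mua, ref_props.musp, fx, ref_props.n)
    floor = REFERENCE_FLOOR * np.nanmax(mac_ref) if mac_ref.size else 0.0
    mask = np.isfinite(mac_ref) & np.isfinite(mac_sample) & (mac_ref > floor)
    n_bad = int(mask.size - mask.sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} pixels masked at fx={fx:g} cm^-1 (reference amplitude below floor)",
            stacklevel=2,
        )
    rd = np.full(mac_sample.shape, np.nan)
    rd[mask] = mac_sample[mask] / mac_ref[mask] * rd_ref
    return rd, mask


@dataclass
class DemodulatedReflectance:
    """Per-pixel calibrated diffuse reflectance versus spatial frequency.

    ``rd`` maps (wavelength, fx) to calibrated reflectance (NaN where the
    mask is false), ``mac_raw`` keeps the raw modulation amplitudes, and
    ``mask`` flags pixels valid at every frequency of a wavelength.
    """

    rd: dict  # (wavelength, fx) -> 2-D array
    mac_raw: dict = field(default_factory=dict)
    mask: dict = field(default_factory=dict)  # wavelength -> 2-D bool array

    @property
    def wavelengths(self) -> tuple:
        return tuple(sorted({k[0] for k in self.rd}))

    def frequencies(self, wavelength: float) -> tuple:
        return tuple(sorted(fx for (wl, fx) in self.rd if wl == wavelength))

    def rd_cube(self, wavelength: float) -> tuple[np.ndarray, np.ndarray]:
        """Stack Rd images at one wavelength into (n_fx, rows, cols) + fx array."""
        fxs = self.frequencies(wavelength)
        cube = np.stack([self.rd[(wavelength, fx)] for fx in fxs])
        return cube, np.asarray(fxs)

    # -- HDF5 round trip ---------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for (wl, fx), arr in self.rd.items():
                f.create_dataset(f"rd/{wl:g}/{fx:.6f}", data=arr)
            for (wl, fx), arr in self.mac_raw.items():
                f.create_dataset(f"mac/{wl:g}/{fx:.6f}", data=arr)
            for wl, m in self.mask.items():
                f.create_dataset(f"mask/{wl:g}", data=m)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "DemodulatedReflectance":
        import h5py

        rd, mac, mask = {}, {}, {}
        with h5py.File(path, "r") as f:
            for wl in f.get("rd", {}):
                for fx in f[f"rd/{wl}"]:
                    rd[(float(wl), float(fx))] = f[f"rd/{wl}/{fx}"][()]
            for wl in f.get("mac", {}):
                for fx in f[f"mac/{wl}"]:
                    mac[(float(wl), float(fx))] = f[f"mac/{wl}/{fx}"][()]
            for wl in f.get("mask", {}):
                mask[float(wl)] = f[f"mask/{wl}"][()].astype(bool)
        return cls(rd=rd, mac_raw=mac, mask=mask)


def calibrate_stack(
    stack: AcquisitionStack, reference: ReferencePhantom
) -> DemodulatedReflectance:
    """Demodulate and calibrate a full acquisition against a reference phantom.

    Every (wavelength, frequency) pair present in the sample stack must also
    be present in the reference stack.
    """
    mac_sample = demodulate_stack(stack)
    mac_ref = demodulate_stack(reference.stack)
    rd, masks = {}, {}
    for wl in stack.wavelengths:
        if wl not in reference.props:
            raise ValueError(f"reference phantom has no properties at {wl} nm")
        wl_mask = np.ones(stack.shape, dtype=bool)
        for fx in stack.frequencies:
            if (wl, fx) not in mac_ref:
                raise ValueError(
                    f"reference stack lacks fx={fx:g} cm^-1 at {wl} nm"
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rd_img, m = calibrate_reflectance(
                    mac_sample[(wl, fx)], mac_ref[(wl, fx)], reference.props[wl], fx
                )
            rd[(wl, fx)] = rd_img
            wl_mask &= m
        masks[wl] = wl_mask
        n_bad = int(wl_mask.size - wl_mask.sum())
        if n_bad:
            log.info("calibration masked %d pixels at %g nm", n_bad, wl)
    return DemodulatedReflectance(rd=rd, mac_raw=mac_sample, mask=masks)
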