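"""Attenuation correction, spectral unmixing and absolute concentration calibration.

Raw fluorescence from tissue confounds fluorophore abundance with the
optical properties of the medium: strongly absorbing regions (a
vascularized tumor, say) return less fluorescence per unit fluorophore, and
can even invert the apparent contrast.  The correction divides the raw
signal by the effective path length

    X_1D(ex, em) = k_ex * k_em / (mueff_ex + mueff_em)

computed per pixel from the recovered optical property maps at the
excitation and emission wavelengths (see :func:`sfdiq.forward.effective_pathlength`):

    F_corr = (F_raw - background) / X_1D

Background removal offers two modes: subtracting a pre-injection baseline
frame (or scalar), or nonnegative spectral unmixing of a multichannel
acquisition onto basis spectra (drug, photosensitizer, autofluorescence).
A linear calibration curve fit on phantoms of known concentration then maps
corrected fluorescence to absolute concentration in ug/mL; because the
correction precedes calibration, one curve serves phantoms of differing
optical properties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.optimize import nnls

from . import forward
from .inversion import PropertyMap

__all__ = [
    "CorrectionFactorMap",
    "FluorescenceImage",
    "BasisSpectra",
    "CalibrationCurve",
    "ConcentrationMap",
    "correction_factor",
    "correct_fluorescence",
    "unmix_spectra",
    "fit_calibration",
    "to_concentration",
    "synthetic_basis_spectra",
]

log = logging.getLogger(__name__)


@dataclass
class CorrectionFactorMap:
    """Per-pixel effective fluorescence path length X_1D (cm)."""

    x1d: np.ndarray
    ex_wavelength: float
    em_wavelength: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.isfinite(self.x1d) & (self.x1d > 0)


@dataclass
class FluorescenceImage:
    """A single-channel fluorescence frame (a.u., clipped nonnegative)."""

    f: np.ndarray
    ex_wavelength: float
    em_wavelength: float
    exposure_ms: float = 100.0
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.f = np.clip(np.asarray(self.f, dtype=float), 0.0, None)


@dataclass
class BasisSpectra:
    """Unit-normalized nonnegative emission basis spectra on shared channels."""

    channels: np.ndarray  # channel wavelengths, nm
    spectra: dict  # component name -> spectrum over channels

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        for name, s in self.spectra.items():
            s = np.asarray(s, dtype=float)
            if s.shape != self.channels.shape:
                raise ValueError(f"spectrum {name!r} length mismatch")
            if np.any(s < 0):
                raise ValueError(f"spectrum {name!r} has negative entries")
            norm = np.linalg.norm(s)
            if norm == 0:
                raise ValueError(f"spectrum {name!r} is zero")
            self.spectra[name] = s / norm

    @property
    def names(self) -> list[str]:
        return list(self.spectra)

    def matrix(self) -> np.ndarray:
        """Channels x components design matrix."""
        return np.column_stack([self.spectra[n] for n in self.names])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"wavelength_nm": self.channels, **self.spectra}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BasisSpectra":
        import pandas as pd

        df = pd.read_csv(path)
        channels = df.pop("wavelength_nm").to_numpy()
        return cls(channels=channels, spectra={c: df[c].to_numpy() for c in df.columns})


def synthetic_basis_spectra(channels) -> BasisSpectra:
    """Synthetic stand-in emission basis spectra (no tabulated set is published).

    Gaussian peaks near 590 nm (doxorubicin) and 720 nm (porphyrin-
    phospholipid photosensitizer) plus a broad autofluorescence band.
    """
    ch = np.asarray(channels, dtype=float)
    dox = np.exp(-0.5 * ((ch - 590.0) / 35.0) ** 2)
    pop = np.exp(-0.5 * ((ch - 720.0) / 25.0) ** 2)
    auto = np.exp(-0.5 * ((ch - 620.0) / 110.0) ** 2)
    return BasisSpectra(channels=ch, spectra={"dox": dox, "pop": pop, "auto": auto})


@dataclass
class CalibrationCurve:
    """Linear map from corrected fluorescence (a.u.) to concentration (ug/mL)."""

    slope: float  # a.u. per (ug/mL)
    intercept: float  # a.u.
    r_squared: float
    concentration_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(
            json.dumps(
                {
                    "slope_au_per_ugml": self.slope,
                    "intercept_au": self.intercept,
                    "r_squared": self.r_squared,
                    "concentration_range_ugml": list(self.concentration_range),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        import json

        d = json.loads(Path(path).read_text())
        return cls(
            slope=d["slope_au_per_ugml"],
            intercept=d["intercept_au"],
            r_squared=d["r_squared"],
            concentration_range=tuple(d["concentration_range_ugml"]),
        )


@dataclass
class ConcentrationMap:
    """Absolute fluorophore concentration per pixel (ug/mL)."""

    c: np.ndarray
    fluorophore: str
    mask: np.ndarray | None = None
    n_clipped: int = 0  # pixels clipped up to zero

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.isfinite(self.c)


def correction_factor(props_ex: PropertyMap, props_em: PropertyMap) -> CorrectionFactorMap:
    """Effective path length X_1D(ex, em) from recovered property maps.

    Invalid pixels of either map propagate into the union mask; absorption
    below the floor of :func:`sfdiq.forward.effective_pathlength` is clamped
    so near-transparent pixels stay finite.
    """
    if props_ex.shape != props_em.shape:
        raise ValueError("excitation/emission property map shapes differ")
    mask = props_ex.mask & props_em.mask
    with np.errstate(invalid="ignore"):
        x1d = forward.effective_pathlength(
            props_ex.mua_map, props_ex.musp_map, props_em.mua_map, props_em.musp_map
        )
    x1d = np.where(mask, x1d, np.nan)
    return CorrectionFactorMap(
        x1d=x1d,
        ex_wavelength=props_ex.wavelength,
        em_wavelength=props_em.wavelength,
        mask=mask,
    )


def correct_fluorescence(
    f_raw: FluorescenceImage,
    x1d: CorrectionFactorMap,
    background: FluorescenceImage | np.ndarray | float = 0.0,
) -> FluorescenceImage:
    """F_corr = (F_raw - background) / X_1D, clipped at zero.

    ``background`` may be a scalar, an array, or a pre-injection
    :class:`FluorescenceImage`; pixels where the correction factor is
    invalid come out NaN.
    """
    if isinstance(background, FluorescenceImage):
        background = background.f
    bg = np.asarray(background, dtype=float)
    if f_raw.f.shape != x1d.x1d.shape:
        raise ValueError("fluorescence and correction factor shapes differ")
    net = f_raw.f - bg
    if np.all(net <= 0):
        warnings.warn("background exceeds signal everywhere; corrected image is zero",
                      stacklevel=2)
    net = np.clip(net, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(x1d.mask, net / x1d.x1d, np.nan)
    # np.clip in __post_init__ passes NaN through, so masked pixels stay NaN
    return FluorescenceImage(
        f=out,
        ex_wavelength=f_raw.ex_wavelength,
        em_wavelength=f_raw.em_wavelength,
        exposure_ms=f_raw.exposure_ms,
        background_subtracted=True,
    )


def unmix_spectra(multichannel, basis: BasisSpectra):
    """Per-pixel nonnegative least-squares unmixing onto basis spectra.

    Parameters
    ----------
    multichannel
        Sequence of :class:`FluorescenceImage` (or arrays), one per basis
        channel, all the same shape; must have at least as many channels as
        basis components.

    Returns
    -------
    amplitudes : dict component -> 2-D amplitude image
    residual : 2-D RMS residual map
    """
    imgs = [im.f if isinstance(im, FluorescenceImage) else np.asarray(im, float)
            for im in multichannel]
    if len(imgs) != len(basis.channels):
        raise ValueError(
            f"{len(imgs)} channel images for {len(basis.channels)} basis channels"
        )
    if len(imgs) < len(basis.names):
        raise ValueError("need at least as many channels as basis components")
    a = basis.matrix()
    if np.linalg.matrix_rank(a) < a.shape[1]:
        raise ValueError("basis spectra are linearly dependent over these channels")
    shape = imgs[0].shape
    y = np.stack([im.ravel() for im in imgs])  # (channels, N)
    coeffs = np.empty((a.shape[1], y.shape[1]))
    resid = np.empty(y.shape[1])
    for p in range(y.shape[1]):
        coeffs[:, p], rnorm = nnls(a, y[:, p])
        resid[p] = rnorm / np.sqrt(a.shape[0])
    amplitudes = {
        name: coeffs[i].reshape(shape) for i, name in enumerate(basis.names)
    }
    return amplitudes, resid.reshape(shape)


def fit_calibration(concentrations, f_corr_values) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, corrected signal)."""
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(f_corr_values, dtype=float)
    if c.shape != f.shape:
        raise ValueError("concentration and fluorescence vectors differ in length")
    if np.unique(c).size < 2:
        raise ValueError("need at least two distinct concentrations")
    res = stats.linregress(c, f)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        concentration_range=(float(c.min()), float(c.max())),
    )


def to_concentration(
    f_corr: FluorescenceImage, curve: CalibrationCurve, fluorophore: str = "fluorophore"
) -> ConcentrationMap:
    """Invert the calibration line: C = (F_corr - intercept) / slope, clipped at 0."""
    c = (f_corr.f - curve.intercept) / curve.slope
    finite = np.isfinite(c)
    n_clipped = int(np.sum(c[finite] < 0))
    if n_clipped:
        log.info("clipped %d negative concentration estimates to zero", n_clipped)
    lo, hi = curve.concentration_range
    with np.errstate(invalid="ignore"):
        n_outside = int(np.sum((c[finite] < lo) | (c[finite] > hi)))
    if n_outside:
        log.info("%d pixels fall outside the calibrated range [%g, %g] ug/mL",
                 n_outside, lo, hi)
    c = np.where(finite, np.clip(c, 0.0, None), np.nan)
    return ConcentrationMap(c=c, fluorophore=fluorophore, mask=finite, n_clipped=n_clipped)
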