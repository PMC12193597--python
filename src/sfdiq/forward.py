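"""Diffusion-approximation forward model for spatially modulated diffuse reflectance.

The core quantity is the diffuse reflectance ``Rd(fx)`` of a semi-infinite
homogeneous turbid medium illuminated by a sinusoidal pattern of spatial
frequency ``fx`` (cm^-1).  In the standard-diffusion picture the modulated
illumination acts like a planar source whose effective attenuation is

    mueff'(fx) = sqrt(mueff^2 + (2*pi*fx)^2),   mueff = sqrt(3*mua*mutr),

with ``mutr = mua + musp`` the transport coefficient, so reflectance falls
off with frequency at a rate set jointly by absorption and scattering.  That
differential sensitivity is what lets multi-frequency reflectance separate
``mua`` from ``musp``.

Closed form used here (partial-current boundary condition):

    Rd(fx) = 3*A*a' / [(mueff'/mutr + 1) * (mueff'/mutr + 3*A)]

where ``a' = musp/mutr`` is the reduced albedo and ``A`` encodes the
refractive-index mismatch through the effective internal reflection
coefficient ``Reff(n)``.  At ``fx = 0`` and ``mua = 0`` the form reduces to
``Rd = 1`` (all photons eventually re-emitted).

This module also hosts the effective-path-length factor used for
fluorescence attenuation correction, so the synthetic data generator and the
correction stage share one set of optics by construction.

All coefficients are in cm^-1, spatial frequencies in cm^-1, path lengths in
cm.  Functions broadcast over numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "effective_reflection_coefficient",
    "boundary_coefficient",
    "diffuse_reflectance",
    "effective_attenuation",
    "fluence_buildup_factor",
    "effective_pathlength",
    "MUA_FLOOR",
]

DEFAULT_INDEX = 1.4

# Floor applied to mua when evaluating the fluorescence path-length factor;
# keeps X_1D finite for near-transparent pixels.
MUA_FLOOR = 0.01


def effective_reflection_coefficient(n: float = DEFAULT_INDEX) -> float:
    """Effective internal reflection coefficient Reff for a tissue/air boundary.

    Polynomial fit in the relative refractive index ``n``; for ``n = 1.4``
    (typical soft tissue) Reff is about 0.53.
    """
    return 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2


def boundary_coefficient(n: float = DEFAULT_INDEX) -> float:
    """Boundary coefficient A = (1 - Reff) / (2 * (1 + Reff))."""
    reff = effective_reflection_coefficient(n)
    return (1.0 - reff) / (2.0 * (1.0 + reff))


def _validate(mua, musp, fx) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    fx = np.asarray(fx, dtype=float)
    if np.any(musp <= 0):
        raise ValueError("reduced scattering coefficient musp must be positive")
    if np.any(mua < 0):
        raise ValueError("absorption coefficient mua must be nonnegative")
    if np.any(fx < 0):
        raise ValueError("spatial frequency fx must be nonnegative")
    return mua, musp, fx


def diffuse_reflectance(mua, musp, fx, n: float = DEFAULT_INDEX):
    """Spatially modulated diffuse reflectance Rd(fx) of a homogeneous medium.

    Parameters
    ----------
    mua, musp
        Absorption and reduced scattering coefficients (cm^-1). Broadcastable.
    fx
        Spatial frequency of the projected sinusoid (cm^-1). Broadcastable.
    n
        Tissue refractive index.

    Returns
    -------
    Rd in [0, 1], decreasing in ``fx`` and ``mua``, increasing in ``musp``.
    """
    mua, musp, fx = _validate(mua, musp, fx)
    mutr = mua + musp
    albedo = musp / mutr
    mueff = np.sqrt(3.0 * mua * mutr)
    mueff_fx = np.sqrt(mueff**2 + (2.0 * np.pi * fx) ** 2)
    a = boundary_coefficient(n)
    ratio = mueff_fx / mutr
    rd = 3.0 * a * albedo / ((ratio + 1.0) * (ratio + 3.0 * a))
    return rd if rd.ndim else float(rd)


def effective_attenuation(mua, musp):
    """mueff = sqrt(3 * mua * (mua + musp)), cm^-1."""
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    return np.sqrt(3.0 * mua * (mua + musp))


def fluence_buildup_factor(mua, musp, n: float = DEFAULT_INDEX):
    """Dimensionless surface fluence build-up factor k for one wavelength.

    Derived from the fx = 0 diffusion solution at the boundary:
    ``k = 3 * a' * A / (1 + mueff/mutr)``.  It scales the exponential depth
    profile ``k * exp(-mueff * z)`` used for both excitation penetration and
    emission escape. Constants are pinned here so an alternative
    literature coefficient set can be swapped in at a single point.
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    mutr = mua + musp
    albedo = musp / mutr
    mueff = effective_attenuation(mua, musp)
    a = boundary_coefficient(n)
    return 3.0 * albedo * a / (1.0 + mueff / mutr)


def effective_pathlength(mua_ex, musp_ex, mua_em, musp_em, n: float = DEFAULT_INDEX,
                         mua_floor: float = MUA_FLOOR):
    """Effective fluorescence path length X_1D(ex, em) in cm.

    Depth integral of an exponential excitation fluence
    ``phi_ex(z) = k_ex * exp(-mueff_ex * z)`` against an exponential emission
    escape function ``E_em(z) = k_em * exp(-mueff_em * z)``:

        X_1D = k_ex * k_em / (mueff_ex + mueff_em)

    Dividing a raw fluorescence image by this factor removes the bias that
    tissue absorption and scattering at the excitation and emission
    wavelengths impose on the apparent fluorophore distribution.  The factor
    is symmetric under exchanging the (ex) and (em) property pairs and
    strictly decreasing in either absorption coefficient.

    ``mua`` values below ``mua_floor`` (cm^-1) are clamped so the factor
    stays finite in the vanishing-attenuation limit.
    """
    mua_ex = np.maximum(np.asarray(mua_ex, dtype=float), mua_floor)
    mua_em = np.maximum(np.asarray(mua_em, dtype=float), mua_floor)
    musp_ex = np.asarray(musp_ex, dtype=float)
    musp_em = np.asarray(musp_em, dtype=float)
    if np.any(musp_ex <= 0) or np.any(musp_em <= 0):
        raise ValueError("musp must be positive at both wavelengths")
    k_ex = fluence_buildup_factor(mua_ex, musp_ex, n)
    k_em = fluence_buildup_factor(mua_em, musp_em, n)
    me_ex = effective_attenuation(mua_ex, musp_ex)
    me_em = effective_attenuation(mua_em, musp_em)
    x = k_ex * k_em / (me_ex + me_em)
    return x if np.ndim(x) else float(x)
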