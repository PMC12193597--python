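"""Synthetic scenes and simulated SFDI acquisitions.

A :class:`SceneSpec` describes a ground-truth sample: a pixel grid covered by
labelled regions, each carrying per-wavelength optical properties
(absorption ``mua`` and reduced scattering ``musp``, cm^-1) and per-
fluorophore concentrations (ug/mL).  From a scene the module simulates

* structured-illumination reflectance stacks — three phase-shifted
  sinusoidal projections per spatial frequency and wavelength, with the
  pattern amplitude scaled by the diffusion-model diffuse reflectance of the
  local optical properties; and
* raw fluorescence images — concentration times the effective-path-length
  attenuation factor, plus tissue autofluorescence.

Both simulators share the forward optics in :mod:`sfdiq.forward` with the
inversion and correction stages, so noise-free round trips recover the
ground truth exactly; noise (shot, read, multiplicative) is optional and
seed-controlled.

Two acquisition protocols are bundled: a wide-field bench protocol
(4 wavelengths, 22 spatial frequencies spanning 0-3.1764 cm^-1) and a
laparoscopic protocol (3 wavelengths, 5 frequencies spanning 0-2.0 cm^-1),
both with three projection phases (0, 2pi/3, 4pi/3).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from matplotlib.path import Path as MplPath

from . import forward

__all__ = [
    "OpticalProperties",
    "SpatialFrequencySet",
    "Region",
    "SceneSpec",
    "AcquisitionStack",
    "ReferencePhantom",
    "THREE_PHASES",
    "WIDEFIELD_WAVELENGTHS",
    "LAPAROSCOPIC_WAVELENGTHS",
    "widefield_frequencies",
    "laparoscopic_frequencies",
    "forward_reflectance",
    "build_scene",
    "simulate_acquisition",
    "simulate_fluorescence",
    "make_reference_phantom",
    "write_stack",
    "read_stack",
]

THREE_PHASES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)

WIDEFIELD_WAVELENGTHS = (590.0, 625.0, 660.0, 740.0)
LAPAROSCOPIC_WAVELENGTHS = (490.0, 590.0, 656.0)


def widefield_frequencies() -> np.ndarray:
    """22 spatial frequencies spanning 0 to 3.1764 cm^-1 (wide-field protocol)."""
    return np.linspace(0.0, 3.1764, 22)


def laparoscopic_frequencies() -> np.ndarray:
    """5 spatial frequencies spanning 0 to 2.0 cm^-1 (laparoscopic protocol)."""
    return np.linspace(0.0, 2.0, 5)


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of a homogeneous medium at one wavelength."""

    mua: float  # absorption coefficient, cm^-1
    musp: float  # reduced scattering coefficient, cm^-1
    wavelength: float  # nm
    n: float = forward.DEFAULT_INDEX  # refractive index

    def __post_init__(self) -> None:
        if self.musp <= 0:
            raise ValueError(f"musp must be positive, got {self.musp}")
        if self.mua < 0:
            raise ValueError(f"mua must be nonnegative, got {self.mua}")
        if self.mua > 0 and self.musp / self.mua < 1.0:
            warnings.warn(
                f"musp/mua = {self.musp / self.mua:.2f} < 1: diffusion model "
                "validity is questionable at this albedo",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SpatialFrequencySet:
    """Projected spatial frequencies (cm^-1) and phase offsets (rad)."""

    frequencies: tuple
    phases: tuple = THREE_PHASES

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        phases = tuple(float(p) for p in self.phases)
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "phases", phases)
        if len(freqs) == 0:
            raise ValueError("frequency set must be nonempty")
        if freqs[0] != 0.0:
            raise ValueError("first spatial frequency must be 0 (planar projection)")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("spatial frequencies must be strictly ascending")
        if len(phases) < 3:
            raise ValueError("need at least three phases for demodulation")

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass
class Region:
    """One scene region: geometry plus per-wavelength properties and concentrations.

    ``geometry`` is one of
      {"type": "full"}
      {"type": "ellipse", "center": [row, col], "axes": [a_row, a_col]}  (pixels)
      {"type": "polygon", "vertices": [[row, col], ...]}                 (pixels)
      {"type": "mask", "mask": 2-D bool array}
    """

    label: str
    geometry: dict
    props: dict = field(default_factory=dict)  # wavelength -> OpticalProperties
    concentrations: dict = field(default_factory=dict)  # fluorophore -> ug/mL

    def __post_init__(self) -> None:
        self.props = {float(w): p for w, p in self.props.items()}
        for c in self.concentrations.values():
            if c < 0:
                raise ValueError("concentrations must be nonnegative")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        kind = self.geometry["type"]
        if kind == "full":
            return np.ones(shape, dtype=bool)
        if kind == "ellipse":
            cr, cc = self.geometry["center"]
            ar, ac = self.geometry["axes"]
            rr, cc_grid = np.mgrid[0 : shape[0], 0 : shape[1]]
            return ((rr - cr) / ar) ** 2 + ((cc_grid - cc) / ac) ** 2 <= 1.0
        if kind == "polygon":
            verts = np.asarray(self.geometry["vertices"], dtype=float)
            area2 = np.sum(
                verts[:, 0] * np.roll(verts[:, 1], -1)
                - np.roll(verts[:, 0], -1) * verts[:, 1]
            )
            if area2 < 0:  # canonical winding for orientation-stable boundaries
                verts = verts[::-1]
            # pixel-center even-odd containment, (row, col) vertex order
            path = MplPath(verts[:, ::-1])
            rr, cc_grid = np.mgrid[0 : shape[0], 0 : shape[1]]
            pts = np.column_stack([cc_grid.ravel(), rr.ravel()])
            return path.contains_points(pts, radius=1e-9).reshape(shape)
        if kind == "mask":
            m = np.asarray(self.geometry["mask"], dtype=bool)
            if m.shape != tuple(shape):
                raise ValueError("mask geometry shape mismatch")
            return m
        raise ValueError(f"unknown geometry type {kind!r}")


@dataclass
class SceneSpec:
    """Ground-truth synthetic scene specification.

    Later regions override earlier ones on overlap; together the regions
    must cover every pixel.  ``fluorescence_gain`` converts concentration
    times path length into detector counts (a.u. per (ug/mL * cm));
    ``autofluorescence_level`` is an additive emission-channel offset (a.u.).
    Noise: ``shot_scale`` (variance per count), ``read_sd`` (a.u.),
    ``mult_sd`` (fractional multiplicative sd); all default off.
    """

    shape: tuple[int, int]
    pixel_size_mm: float
    regions: list
    autofluorescence_level: float = 0.0
    fluorescence_gain: float = 1.0
    noise: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = (int(self.shape[0]), int(self.shape[1]))
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if not self.regions:
            raise ValueError("scene needs at least one region")
        unknown = set(self.noise) - {"shot_scale", "read_sd", "mult_sd"}
        if unknown:
            raise ValueError(f"unknown noise keys: {sorted(unknown)}")

    @property
    def wavelengths(self) -> tuple:
        wls: set[float] = set()
        for r in self.regions:
            wls.update(r.props)
        return tuple(sorted(wls))

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "shape": list(self.shape),
            "pixel_size_mm": self.pixel_size_mm,
            "autofluorescence_level": self.autofluorescence_level,
            "fluorescence_gain": self.fluorescence_gain,
            "noise": dict(self.noise),
            "seed": int(self.seed),
            "regions": [
                {
                    "label": r.label,
                    "geometry": {
                        k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in r.geometry.items()
                    },
                    "props": {
                        str(w): {"mua": p.mua, "musp": p.musp, "n": p.n}
                        for w, p in r.props.items()
                    },
                    "concentrations": dict(r.concentrations),
                }
                for r in self.regions
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneSpec":
        doc = yaml.safe_load(Path(path).read_text())
        regions = []
        for r in doc["regions"]:
            geom = dict(r["geometry"])
            if geom["type"] == "mask":
                geom["mask"] = np.asarray(geom["mask"], dtype=bool)
            props = {
                float(w): OpticalProperties(
                    mua=p["mua"], musp=p["musp"], wavelength=float(w), n=p.get("n", forward.DEFAULT_INDEX)
                )
                for w, p in r["props"].items()
            }
            regions.append(
                Region(label=r["label"], geometry=geom, props=props,
                       concentrations=dict(r.get("concentrations", {})))
            )
        return cls(
            shape=tuple(doc["shape"]),
            pixel_size_mm=doc["pixel_size_mm"],
            regions=regions,
            autofluorescence_level=doc.get("autofluorescence_level", 0.0),
            fluorescence_gain=doc.get("fluorescence_gain", 1.0),
            noise=doc.get("noise", {}),
            seed=doc.get("seed", 0),
        )


@dataclass
class AcquisitionStack:
    """Raw images indexed by (wavelength nm, spatial frequency cm^-1, phase rad)."""

    images: dict  # (wavelength, fx, phase) -> 2-D array
    pixel_size_mm: float
    exposure_ms: float = 100.0
    binning: int = 1
    protocol_tag: str = "widefield"
    seed: int | None = None

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent image shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    @property
    def wavelengths(self) -> tuple:
        return tuple(sorted({k[0] for k in self.images}))

    @property
    def frequencies(self) -> tuple:
        return tuple(sorted({k[1] for k in self.images}))

    @property
    def phases(self) -> tuple:
        return tuple(sorted({k[2] for k in self.images}))

    def image(self, wavelength: float, fx: float, phase: float) -> np.ndarray:
        return self.images[(wavelength, fx, phase)]

    def phase_images(self, wavelength: float, fx: float) -> list[np.ndarray]:
        return [self.images[(wavelength, fx, p)] for p in self.phases]

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class ReferencePhantom:
    """Homogeneous phantom of known optical properties with its simulated stack."""

    props: dict  # wavelength -> OpticalProperties
    stack: AcquisitionStack

    def __post_init__(self) -> None:
        self.props = {float(w): p for w, p in self.props.items()}
        missing = set(self.stack.wavelengths) - set(self.props)
        if missing:
            raise ValueError(f"reference properties missing for wavelengths {sorted(missing)}")


# re-exported so downstream stages and scenes share one forward model
def forward_reflectance(props: OpticalProperties, fx) -> float:
    """Diffuse reflectance Rd(fx) for homogeneous properties (see sfdiq.forward)."""
    return forward.diffuse_reflectance(props.mua, props.musp, fx, props.n)


def build_scene(spec: SceneSpec, wavelengths=None):
    """Rasterize a scene into per-wavelength property maps and concentration maps.

    Returns
    -------
    props_maps : dict wavelength -> (mua_map, musp_map)
    conc_maps : dict fluorophore -> concentration map (ug/mL)
    """
    if wavelengths is None:
        wavelengths = spec.wavelengths
    wavelengths = [float(w) for w in wavelengths]
    shape = spec.shape
    coverage = np.zeros(shape, dtype=bool)
    masks = []
    for region in spec.regions:
        m = region.mask(shape)
        masks.append(m)
        coverage |= m
    if not coverage.all():
        raise ValueError("regions do not cover every pixel of the scene")

    props_maps = {}
    for wl in wavelengths:
        mua_map = np.zeros(shape)
        musp_map = np.zeros(shape)
        for region, m in zip(spec.regions, masks):
            if wl not in region.props:
                raise ValueError(
                    f"region {region.label!r} defines no optical properties at {wl} nm"
                )
            mua_map[m] = region.props[wl].mua
            musp_map[m] = region.props[wl].musp
        props_maps[wl] = (mua_map, musp_map)

    fluors: set[str] = set()
    for region in spec.regions:
        fluors.update(region.concentrations)
    conc_maps = {}
    for name in sorted(fluors):
        cmap = np.zeros(shape)
        for region, m in zip(spec.regions, masks):
            cmap[m] = region.concentrations.get(name, 0.0)
        conc_maps[name] = cmap
    return props_maps, conc_maps


def _apply_noise(img: np.ndarray, noise: dict, rng: np.random.Generator) -> np.ndarray:
    out = img
    mult_sd = noise.get("mult_sd", 0.0)
    if mult_sd:
        out = out * (1.0 + rng.normal(0.0, mult_sd, size=out.shape))
    shot = noise.get("shot_scale", 0.0)
    if shot:
        out = out + rng.normal(0.0, 1.0, size=out.shape) * np.sqrt(shot * np.clip(out, 0, None))
    read_sd = noise.get("read_sd", 0.0)
    if read_sd:
        out = out + rng.normal(0.0, read_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def simulate_acquisition(
    spec: SceneSpec,
    freqs: SpatialFrequencySet,
    wavelengths,
    i0: float = 1000.0,
    exposure_ms: float = 100.0,
    protocol_tag: str = "widefield",
) -> AcquisitionStack:
    """Simulate a structured-illumination reflectance acquisition.

    Each raw image is ``I_k(x) = (I0/2) * [1 + cos(2*pi*fx*x + phi_k)] *
    Rd(fx; props(x))`` with the sinusoid running along image columns
    (``x`` in cm via the scene pixel size), plus optional noise, clipped at
    zero.  Image count is ``|wavelengths| * |frequencies| * |phases|``;
    output is bit-identical for a fixed scene seed.
    """
    wavelengths = [float(w) for w in wavelengths]
    props_maps, _ = build_scene(spec, wavelengths)
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.shape
    x_cm = np.arange(ncols) * (spec.pixel_size_mm / 10.0)
    images = {}
    for wl in wavelengths:
        mua_map, musp_map = props_maps[wl]
        for fx in freqs.frequencies:
            rd = forward.diffuse_reflectance(mua_map, musp_map, fx)
            for phase in freqs.phases:
                pattern = 0.5 * i0 * (1.0 + np.cos(2.0 * np.pi * fx * x_cm + phase))
                img = np.broadcast_to(pattern, (nrows, ncols)) * rd
                images[(wl, fx, phase)] = _apply_noise(img, spec.noise, rng)
    return AcquisitionStack(
        images=images,
        pixel_size_mm=spec.pixel_size_mm,
        exposure_ms=exposure_ms,
        protocol_tag=protocol_tag,
        seed=spec.seed,
    )


def simulate_fluorescence(
    spec: SceneSpec,
    ex_wavelength: float,
    em_wavelength: float,
    fluorophore: str | None = None,
) -> np.ndarray:
    """Simulate a raw (planar-illumination) fluorescence image.

    ``F_raw(x) = gain * C(x) * X_1D(x; ex, em) + autofluorescence + noise``,
    clipped at zero — the same effective-path-length attenuation the
    correction stage divides out, so the noise-free round trip is exact.
    """
    ex_wavelength = float(ex_wavelength)
    em_wavelength = float(em_wavelength)
    props_maps, conc_maps = build_scene(spec, wavelengths=None)
    for wl in (ex_wavelength, em_wavelength):
        if wl not in props_maps:
            raise ValueError(f"scene defines no optical properties at {wl} nm")
    if fluorophore is None:
        if len(conc_maps) != 1:
            raise ValueError(
                f"scene has fluorophores {sorted(conc_maps)}; specify which to image"
            )
        fluorophore = next(iter(conc_maps))
    if fluorophore not in conc_maps:
        raise ValueError(f"scene defines no fluorophore {fluorophore!r}")
    c = conc_maps[fluorophore]
    mua_ex, musp_ex = props_maps[ex_wavelength]
    mua_em, musp_em = props_maps[em_wavelength]
    x1d = forward.effective_pathlength(mua_ex, musp_ex, mua_em, musp_em)
    f = spec.fluorescence_gain * c * x1d + spec.autofluorescence_level
    rng = np.random.default_rng(spec.seed)
    return _apply_noise(f, spec.noise, rng)


def make_reference_phantom(
    props: dict,
    freqs: SpatialFrequencySet,
    shape: tuple[int, int] = (64, 64),
    pixel_size_mm: float = 0.3,
    i0: float = 1000.0,
    protocol_tag: str = "widefield",
) -> ReferencePhantom:
    """Simulate a noise-free homogeneous calibration phantom.

    ``props`` maps wavelength (nm) to the phantom's known
    :class:`OpticalProperties`; the returned bundle pairs those with a
    noise-free acquisition stack for calibration ratioing.
    """
    props = {float(w): p for w, p in props.items()}
    region = Region(label="phantom", geometry={"type": "full"}, props=props)
    spec = SceneSpec(shape=shape, pixel_size_mm=pixel_size_mm, regions=[region], seed=0)
    stack = simulate_acquisition(
        spec, freqs, wavelengths=sorted(props), i0=i0, protocol_tag=protocol_tag
    )
    return ReferencePhantom(props=props, stack=stack)


# ---------------------------------------------------------------------------
# TIFF + JSON manifest round trip
# ---------------------------------------------------------------------------

def write_stack(stack: AcquisitionStack, tiff_path: str | Path, manifest_path: str | Path | None = None):
    """Write a stack as a multi-page 32-bit TIFF plus a JSON sidecar manifest.

    Page order is wavelength-major, then frequency, then phase.
    """
    import tifffile

    tiff_path = Path(tiff_path)
    if manifest_path is None:
        manifest_path = tiff_path.with_suffix(".json")
    pages = [
        stack.images[(wl, fx, ph)].astype(np.float32)
        for wl in stack.wavelengths
        for fx in stack.frequencies
        for ph in stack.phases
    ]
    tifffile.imwrite(tiff_path, np.stack(pages))
    manifest = {
        "wavelengths": list(stack.wavelengths),
        "frequencies_cm1": list(stack.frequencies),
        "phases_rad": list(stack.phases),
        "pixel_size_mm": stack.pixel_size_mm,
        "exposure_ms": stack.exposure_ms,
        "binning": stack.binning,
        "seed": stack.seed,
        "protocol_tag": stack.protocol_tag,
    }
    Path(manifest_path).write_text(json.dumps(manifest, indent=1))
    return tiff_path, Path(manifest_path)


def read_stack(tiff_path: str | Path, manifest_path: str | Path | None = None) -> AcquisitionStack:
    """Read a stack written by :func:`write_stack`; validates page count."""
    import tifffile

    tiff_path = Path(tiff_path)
    if manifest_path is None:
        manifest_path = tiff_path.with_suffix(".json")
    manifest = json.loads(Path(manifest_path).read_text())
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:
        pages = pages[None]
    wls = manifest["wavelengths"]
    fxs = manifest["frequencies_cm1"]
    phs = manifest["phases_rad"]
    expected = len(wls) * len(fxs) * len(phs)
    if pages.shape[0] != expected:
        raise ValueError(
            f"{tiff_path}: manifest promises {expected} pages "
            f"({len(wls)} wavelengths x {len(fxs)} frequencies x {len(phs)} phases), "
            f"file has {pages.shape[0]}"
        )
    images = {}
    i = 0
    for wl in wls:
        for fx in fxs:
            for ph in phs:
                images[(float(wl), float(fx), float(ph))] = np.asarray(pages[i], dtype=float)
                i += 1
    return AcquisitionStack(
        images=images,
        pixel_size_mm=manifest["pixel_size_mm"],
        exposure_ms=manifest.get("exposure_ms", 100.0),
        binning=manifest.get("binning", 1),
        protocol_tag=manifest.get("protocol_tag", "widefield"),
        seed=manifest.get("seed"),
    )
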