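"""Phantoms with metallic inserts and polychromatic projection simulation.

Real polychromatic x-ray beams harden as they traverse dense metal: low
energies are absorbed preferentially, so the measured log-attenuation grows
sub-linearly with path length.  An FBP reconstruction of such data shows the
classic metal artifacts — dark streaks between metal objects and negative
undershoots hugging them.  This module produces exactly that pathology on
demand with a discrete-spectrum Beer–Lambert model:

    I = sum_E  w(E) * exp( - sum_m  mu_m(E) * l_m ),      p = -ln(I)

over a handful of energy levels E with fluence weights w and per-material
attenuation curves mu_m, where l_m is the (equivalent) path length through
material m obtained with the package's own forward projector.  With a
single-energy spectrum the model degenerates to the exact monochromatic line
integral.  Each material's *reference* attenuation is the fluence-weighted
mean of its curve; by Jensen's inequality the polychromatic measurement is
strictly below the reference-energy monochromatic value on any ray with
positive path length, which is the mechanism behind the dark streaks.

The attenuation curves are documented model constants (a water-like soft
material and an iron-like metal), not physical table lookups; scatter,
detector response and photon starvation are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ct_core import fbp, forward_project
from .errors import GenerationError, GeometryError
from .geometry import ScanGeometry
from .metal_trace import segment_metal

__all__ = [
    "Ellipse",
    "MetalDisk",
    "PhantomSpec",
    "SpectrumModel",
    "default_spectrum",
    "make_phantom",
    "ground_truth_image",
    "polychromatic_project",
    "make_scanner_preset",
    "make_test_preset",
    "make_demo_case",
]

#: Transmitted-intensity floor guarding the logarithm against underflow.
INTENSITY_FLOOR = 1e-12


@dataclass(frozen=True)
class Ellipse:
    """Soft-background ellipse: centre/semi-axes in mm, rotation in radians,
    attenuation at the spectrum's reference (effective) energy in 1/mm.

    ``taper`` softens the rim with a cosine roll-off over that fraction of
    the elliptical radius (0 gives a sharp pixel-centre-inclusion edge).
    Soft edges keep FBP ringing away from zero so the negativity the MAR
    algorithm targets stays confined to the metal neighbourhood, as it is
    in real scans.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0
    mu: float = 0.02
    taper: float = 0.0


@dataclass(frozen=True)
class MetalDisk:
    """Metallic insert: centre and radius in mm."""

    center: tuple[float, float]
    radius: float
    material: str = "metal"


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom: background ellipses plus metal disks on a grid.

    ``pedestal_mu`` adds a uniform soft-material attenuation (1/mm at the
    reference energy) over the whole grid — the object sitting in a filled
    tray — so no pixel's true value is zero outside the metal.
    """

    grid: ScanGeometry
    ellipses: tuple[Ellipse, ...] = ()
    metal_disks: tuple[MetalDisk, ...] = ()
    pedestal_mu: float = 0.0
    seed: int | None = None


@dataclass(frozen=True)
class SpectrumModel:
    """Discrete x-ray spectrum and per-material attenuation curves.

    ``energies`` in keV, ``weights`` normalized fluence fractions,
    ``mu_curves`` mapping material name to attenuation (1/mm) at each
    energy; curves must be positive and non-increasing with energy.
    """

    energies: tuple[float, ...]
    weights: tuple[float, ...]
    mu_curves: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.energies) != len(w):
            raise ValueError("energies and weights must have equal length")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        for name, curve in self.mu_curves.items():
            c = np.asarray(curve, dtype=float)
            if len(c) != len(self.energies):
                raise ValueError(f"mu curve for {name!r} has wrong length")
            if np.any(c <= 0):
                raise ValueError(f"mu curve for {name!r} must be positive")
            if np.any(np.diff(c) > 0):
                raise ValueError(f"mu curve for {name!r} must not increase with energy")

    def reference_mu(self, material: str) -> float:
        """Fluence-weighted mean attenuation — the effective-energy value."""
        return float(
            np.dot(np.asarray(self.weights), np.asarray(self.mu_curves[material]))
        )


def default_spectrum() -> SpectrumModel:
    """Five-level spectrum with water-like and iron-like materials.

    Effective attenuations are ~0.021/mm (background) and ~0.45/mm (metal),
    a 22x contrast; the metal curve spans a 13x range across the spectrum so
    rays through metal harden severely.
    """
    return SpectrumModel(
        energies=(40.0, 60.0, 80.0, 100.0, 120.0),
        weights=(0.15, 0.30, 0.30, 0.15, 0.10),
        mu_curves={
            "background": (0.0268, 0.0226, 0.0184, 0.0171, 0.0160),
            "metal": (1.20, 0.55, 0.26, 0.14, 0.09),
        },
    )


def _inside_fov(center: tuple[float, float], extent: float, geom: ScanGeometry) -> bool:
    half = geom.fov / 2.0
    return (abs(center[0]) + extent <= half) and (abs(center[1]) + extent <= half)


def make_phantom(
    spec: PhantomSpec, spectrum: SpectrumModel | None = None
) -> dict[str, np.ndarray]:
    """Rasterize a phantom into per-material equivalent-density maps.

    Pixel-centre inclusion decides membership.  The metal map is a binary
    indicator; the background map holds each ellipse's attenuation divided
    by the background material's reference attenuation (so ``mu * l`` uses a
    single curve per material), with overlapping ellipses adding.  Pixels
    under metal resolve to metal only.
    """
    spectrum = spectrum or default_spectrum()
    geom = spec.grid
    x, y = geom.pixel_coords()
    mu_bg_ref = spectrum.reference_mu("background")
    background = np.full(geom.n_pixels * geom.n_pixels, spec.pedestal_mu / mu_bg_ref)

    for e in spec.ellipses:
        if not _inside_fov(e.center, max(e.semi_axes), geom):
            raise GeometryError(f"ellipse at {e.center} extends outside the FOV")
        dx, dy = x - e.center[0], y - e.center[1]
        c, s = np.cos(e.rotation), np.sin(e.rotation)
        u, v = c * dx + s * dy, -s * dx + c * dy
        rho = np.sqrt((u / e.semi_axes[0]) ** 2 + (v / e.semi_axes[1]) ** 2)
        if e.taper > 0:
            w = np.clip((1.0 - rho) / e.taper, 0.0, 1.0)
            profile = 0.5 - 0.5 * np.cos(np.pi * w)
        else:
            profile = (rho <= 1.0).astype(float)
        background += (e.mu / mu_bg_ref) * profile

    metal = np.zeros_like(background)
    for d in spec.metal_disks:
        if not _inside_fov(d.center, d.radius, geom):
            raise GeometryError(f"metal disk at {d.center} extends outside the FOV")
        inside = (x - d.center[0]) ** 2 + (y - d.center[1]) ** 2 <= d.radius**2
        metal[inside] = 1.0

    background[metal > 0] = 0.0  # solid metal displaces soft material
    shape = geom.image_shape
    return {"background": background.reshape(shape), "metal": metal.reshape(shape)}


def ground_truth_image(
    maps: dict[str, np.ndarray], spectrum: SpectrumModel
) -> np.ndarray:
    """Reference-energy attenuation image implied by the material maps."""
    out = np.zeros_like(next(iter(maps.values())))
    for name, m in maps.items():
        out = out + spectrum.reference_mu(name) * m
    return out


def polychromatic_project(
    maps: dict[str, np.ndarray],
    spectrum: SpectrumModel,
    geom: ScanGeometry,
    *,
    photons: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Beam-hardened sinogram of the material maps.

    Per ray: equivalent path lengths ``l_m`` through every material map via
    the forward projector, transmitted fraction
    ``I = sum_E w(E) exp(-sum_m mu_m(E) l_m)``, sinogram value ``-ln(I)``.
    With a single-energy spectrum this equals the monochromatic line
    integral exactly.  ``photons``, when given, applies Poisson noise to the
    transmitted intensity (counts per ray in air); requires ``rng``.
    """
    missing = set(maps) - set(spectrum.mu_curves)
    if missing:
        raise ValueError(f"no attenuation curve for material(s) {sorted(missing)}")
    lengths = {name: forward_project(m, geom) for name, m in maps.items()}
    intensity = np.zeros(geom.sinogram_shape)
    for i, w in enumerate(spectrum.weights):
        att = np.zeros(geom.sinogram_shape)
        for name, ell in lengths.items():
            att += spectrum.mu_curves[name][i] * ell
        intensity += w * np.exp(-att)
    if photons is not None:
        if rng is None:
            raise ValueError("photons noise requires an rng")
        counts = rng.poisson(photons * intensity)
        intensity = counts / photons
    clipped = np.maximum(intensity, INTENSITY_FLOOR)
    if np.any(intensity < INTENSITY_FLOOR):
        import warnings

        warnings.warn(
            f"transmitted intensity clipped at floor {INTENSITY_FLOOR}", stacklevel=2
        )
    return -np.log(clipped)


def make_scanner_preset() -> ScanGeometry:
    """Scaled-down airport-scanner geometry: 180 views over 180 degrees,
    597 bins at 0.92 mm, 420 x 420 image at 0.92 mm."""
    return ScanGeometry(
        n_views=180, n_bins=597, bin_spacing=0.92, n_pixels=420, pixel_spacing=0.92
    )


def make_test_preset() -> ScanGeometry:
    """Proportionally reduced geometry for fast exercise of the pipeline."""
    return ScanGeometry(
        n_views=90, n_bins=128, bin_spacing=0.92, n_pixels=96, pixel_spacing=0.92
    )


def make_demo_case(
    seed: int,
    geom: ScanGeometry | None = None,
    spectrum: SpectrumModel | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded beam-hardened case: (sinogram, ground-truth image, metal mask).

    A soft tapered oval on a uniform pedestal (the scanned object sitting in
    a filled tray, so true attenuation is positive everywhere), an
    off-centre low-density inclusion, and two metal disks at jittered
    positions.  Generation fails loudly unless the raw FBP of the sinogram
    exhibits negative pixels in the neighbourhood of the metal and the true
    metal attenuation clears three times the 1/3-of-max segmentation
    threshold — the regime the MAR algorithm targets.  Deterministic for a
    given seed.
    """
    geom = geom or make_test_preset()
    spectrum = spectrum or default_spectrum()
    rng = np.random.default_rng(seed)
    scale = geom.fov / 88.32  # proportions defined on the test preset FOV

    jitter = rng.uniform(-2.0, 2.0, size=4) * scale
    body = Ellipse(
        (0.0, 0.0), (40.0 * scale, 32.0 * scale), 0.1, mu=0.010, taper=0.35
    )
    inclusion = Ellipse(
        (-10.0 * scale + jitter[0], 6.0 * scale + jitter[1]),
        (11.0 * scale, 7.0 * scale),
        -0.3,
        mu=-0.008,  # relative: carves a lower-density pocket out of the body
        taper=0.5,
    )
    disks = (
        MetalDisk((13.0 * scale + jitter[2], -5.0 * scale + jitter[3]), 5.5 * scale),
        MetalDisk((-14.0 * scale + jitter[3], -9.0 * scale + jitter[2]), 4.5 * scale),
    )
    spec = PhantomSpec(
        grid=geom,
        ellipses=(body, inclusion),
        metal_disks=disks,
        pedestal_mu=0.012,
    )
    maps = make_phantom(spec, spectrum)
    truth = ground_truth_image(maps, spectrum)
    metal_support = maps["metal"] > 0
    sino = polychromatic_project(maps, spectrum, geom)

    raw = fbp(sino, geom)
    near_metal = ndimage.binary_dilation(metal_support, iterations=8)
    if raw[near_metal].min() >= 0:
        raise GenerationError(
            "raw FBP shows no negative undershoot near the metal inserts"
        )
    threshold = (1.0 / 3.0) * raw.max()
    if truth[metal_support].min() < 3.0 * threshold:
        raise GenerationError(
            "metal attenuation does not clear 3x the segmentation threshold"
        )
    if not segment_metal(raw).any():
        raise GenerationError("segmentation found no metal in the raw image")
    return sino, truth, metal_support
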