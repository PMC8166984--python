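"""Parallel-beam projectors, exact ramp filtration, FBP and its adjoint.

The forward projector is pixel-driven: at each view the centre of every image
pixel projects to a continuous detector coordinate and its value is split
linearly between the two nearest bins, weighted by ``pixel_spacing**2 /
bin_spacing`` (pixel area divided by detector pitch, which turns the
accumulated attenuation-area into a per-bin line integral).  Backprojection
is the literal matrix transpose of that splat, scaled by the view-angle
quadrature weight ``pi / n_views``.  The matched pair is what makes the
projection-domain subgradient in :mod:`negmar.optimize` an exact gradient of
the discrete objective.

The ramp (Ram-Lak) filter is applied with its exact band-limited
spatial-domain taps

    h(0) = 1/4,   h(n) = -1/(n pi)^2  for odd n,   h(n) = 0  for even n != 0,

scaled by ``1 / bin_spacing**2``, with zero extension beyond the detector and
no apodization window.  The FBP operator is ``A = backproject o ramp_filter``
and its adjoint is ``A^T = (pi/n_views) * ramp_filter o forward_project``
(the ramp Toeplitz matrix is symmetric, so A and A^T are true numerical
transposes of one another).
"""

from __future__ import annotations

import functools

import numpy as np

from .errors import GeometryError
from .geometry import ScanGeometry

__all__ = [
    "make_ramp_kernel",
    "ramp_filter",
    "forward_project",
    "backproject",
    "fbp",
    "fbp_adjoint",
]


def make_ramp_kernel(n_bins: int) -> np.ndarray:
    """Exact Ram-Lak convolution taps for lags ``-(n_bins-1) .. n_bins-1``.

    Returned in unit-sample-spacing form; the physical ``1/bin_spacing**2``
    scaling is applied at filtration time.

    Parameters
    ----------
    n_bins:
        Detector bins per view; the kernel has ``2*n_bins - 1`` taps with the
        zero-lag tap at index ``n_bins - 1``.
    """
    if not isinstance(n_bins, (int, np.integer)) or n_bins < 1:
        raise GeometryError(f"n_bins must be a positive integer, got {n_bins!r}")
    lags = np.arange(-(n_bins - 1), n_bins)
    taps = np.zeros(2 * n_bins - 1)
    taps[lags == 0] = 0.25
    odd = lags % 2 != 0
    taps[odd] = -1.0 / (lags[odd] * np.pi) ** 2
    return taps


@functools.lru_cache(maxsize=8)
def _ramp_matrix(n_bins: int) -> np.ndarray:
    """Symmetric Toeplitz matrix of the ramp convolution (zero extension)."""
    taps = make_ramp_kernel(n_bins)
    idx = np.arange(n_bins)
    # H[b, n] = h(b - n); lag index offset by n_bins - 1.
    return taps[idx[:, None] - idx[None, :] + n_bins - 1]


def ramp_filter(sino: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    """Convolve each view row with the exact ramp taps.

    Zero extension beyond the detector, same-size output, scaled by
    ``1 / bin_spacing**2``.  Linear in the input.
    """
    sino = geom.check_sinogram(sino)
    H = _ramp_matrix(geom.n_bins)
    return (sino @ H) / geom.bin_spacing**2


def _splat_coords(geom: ScanGeometry, theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Continuous bin coordinate of every pixel centre at one view angle."""
    x, y = geom.pixel_coords()
    t = x * np.cos(theta) + y * np.sin(theta)
    return t / geom.bin_spacing + (geom.n_bins - 1) / 2.0, t


def forward_project(img: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    """Discrete line integrals of ``img`` along every (view, bin) ray.

    Row ``v``, bin ``b`` approximates the integral of the image along the ray
    at angle ``v*pi/n_views`` and signed detector offset
    ``(b - (n_bins-1)/2) * bin_spacing``.  Rays beyond the image support
    contribute zero.  Linear in ``img``.
    """
    img = geom.check_image(img)
    flat = img.ravel()
    weight = geom.pixel_spacing**2 / geom.bin_spacing
    sino = np.empty(geom.sinogram_shape)
    nb = geom.n_bins
    for v, theta in enumerate(geom.angles):
        u, _ = _splat_coords(geom, theta)
        i0 = np.floor(u).astype(np.intp)
        frac = u - i0
        i1 = i0 + 1
        m0 = (i0 >= 0) & (i0 < nb)
        m1 = (i1 >= 0) & (i1 < nb)
        row = np.bincount(i0[m0], weights=(flat * (1.0 - frac))[m0], minlength=nb)
        row += np.bincount(i1[m1], weights=(flat * frac)[m1], minlength=nb)
        sino[v] = row * weight
    return sino


def backproject(sino: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    """Adjoint of :func:`forward_project`, scaled by ``pi / n_views``.

    Each pixel gathers the linear interpolation of the view row at its
    projected detector coordinate; this is exactly the transpose of the
    forward splat, times the view-angle quadrature weight.
    """
    sino = geom.check_sinogram(sino)
    weight = geom.pixel_spacing**2 / geom.bin_spacing
    nb = geom.n_bins
    acc = np.zeros(geom.n_pixels * geom.n_pixels)
    for v, theta in enumerate(geom.angles):
        u, _ = _splat_coords(geom, theta)
        i0 = np.floor(u).astype(np.intp)
        frac = u - i0
        i1 = i0 + 1
        m0 = (i0 >= 0) & (i0 < nb)
        m1 = (i1 >= 0) & (i1 < nb)
        row = sino[v]
        acc[m0] += row[i0[m0]] * (1.0 - frac[m0])
        acc[m1] += row[i1[m1]] * frac[m1]
    acc *= weight * geom.angular_range / geom.n_views
    return acc.reshape(geom.image_shape)


def fbp(sino: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    """Filtered backprojection: the reconstruction operator ``A``."""
    return backproject(ramp_filter(sino, geom), geom)


def fbp_adjoint(img: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    """Adjoint ``A^T`` of FBP: forward projection followed by ramp filtration.

    Carries the same ``pi / n_views`` quadrature factor as
    :func:`backproject`, so ``<fbp(s), x> == <s, fbp_adjoint(x)>`` holds to
    floating-point rounding.
    """
    out = ramp_filter(forward_project(img, geom), geom)
    out *= geom.angular_range / geom.n_views
    return out
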