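"""Parallel-beam scan geometry and array validation.

Conventions used throughout the package:

* The image is a square ``n_pixels x n_pixels`` array of linear attenuation
  values (1/mm).  The origin sits at the grid centre; column index grows with
  +x, row index grows with +y; pixel centres are at
  ``(idx - (n_pixels - 1)/2) * pixel_spacing`` mm.
* A sinogram is an ``n_views x n_bins`` array of line integrals
  (dimensionless attenuation x length).  View ``v`` is acquired at angle
  ``v * pi / n_views`` over the half-open range [0, pi).  The detector
  coordinate of a point (x, y) at angle theta is ``t = x cos(theta) +
  y sin(theta)``; bin ``b`` is centred at ``(b - (n_bins - 1)/2) *
  bin_spacing`` mm, i.e. the detector is centred on the rotation axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, NonFiniteError

__all__ = ["ScanGeometry"]


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam acquisition and reconstruction grid parameters.

    Parameters
    ----------
    n_views:
        Number of projection angles, uniformly covering [0, pi).
    n_bins:
        Detector bins per view.
    bin_spacing:
        Detector sample pitch in mm.
    n_pixels:
        Side length of the square reconstruction grid, in pixels.
    pixel_spacing:
        Image sample pitch in mm.
    angular_range:
        Angle span in radians.  Fixed at pi for this tool.
    """

    n_views: int
    n_bins: int
    bin_spacing: float
    n_pixels: int
    pixel_spacing: float
    angular_range: float = field(default=math.pi)

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise GeometryError(f"n_views must be >= 1, got {self.n_views}")
        if self.n_bins < 1:
            raise GeometryError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.n_pixels < 1:
            raise GeometryError(f"n_pixels must be >= 1, got {self.n_pixels}")
        if not self.bin_spacing > 0:
            raise GeometryError(f"bin_spacing must be > 0, got {self.bin_spacing}")
        if not self.pixel_spacing > 0:
            raise GeometryError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        if not math.isclose(self.angular_range, math.pi):
            raise GeometryError("angular_range is fixed at pi (180 degrees)")

    @property
    def angles(self) -> np.ndarray:
        """View angles in radians, half-open [0, pi)."""
        return np.arange(self.n_views) * (self.angular_range / self.n_views)

    @property
    def image_shape(self) -> tuple[int, int]:
        return (self.n_pixels, self.n_pixels)

    @property
    def sinogram_shape(self) -> tuple[int, int]:
        return (self.n_views, self.n_bins)

    @property
    def fov(self) -> float:
        """Image field-of-view side length in mm."""
        return self.n_pixels * self.pixel_spacing

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (x, y) pixel-centre coordinates in mm, C order."""
        c = (self.n_pixels - 1) / 2.0
        axis = (np.arange(self.n_pixels) - c) * self.pixel_spacing
        yy, xx = np.meshgrid(axis, axis, indexing="ij")
        return xx.ravel(), yy.ravel()

    def bin_offsets(self) -> np.ndarray:
        """Signed detector bin-centre offsets in mm."""
        c = (self.n_bins - 1) / 2.0
        return (np.arange(self.n_bins) - c) * self.bin_spacing

    # -- validation helpers ------------------------------------------------

    def check_image(self, img: np.ndarray, *, name: str = "image") -> np.ndarray:
        img = np.asarray(img, dtype=np.float64)
        if img.shape != self.image_shape:
            raise GeometryError(
                f"{name} shape {img.shape} does not match grid {self.image_shape}"
            )
        if not np.all(np.isfinite(img)):
            raise NonFiniteError(f"{name} contains non-finite values")
        return img

    def check_sinogram(self, sino: np.ndarray, *, name: str = "sinogram") -> np.ndarray:
        sino = np.asarray(sino, dtype=np.float64)
        if sino.shape != self.sinogram_shape:
            raise GeometryError(
                f"{name} shape {sino.shape} does not match geometry "
                f"{self.sinogram_shape}"
            )
        if not np.all(np.isfinite(sino)):
            raise NonFiniteError(f"{name} contains non-finite values")
        return sino
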