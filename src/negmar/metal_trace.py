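"""Metal segmentation and metal-trace identification in the sinogram.

The optimization variables of the MAR algorithm are the metal-affected
projection values ``P_M``.  They are identified in three steps: reconstruct
a raw FBP image from the measured sinogram, threshold it at a fraction
(default 1/3) of its maximum to obtain a metal-only image, and forward
project that metal-only image — every sinogram entry receiving a positive
contribution is flagged as metal-affected.  The complement ``P_notM`` is
never updated; the restriction operator ``D`` is implemented as masking, so
sinogram shape is preserved throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ct_core import forward_project
from .errors import GeometryError, NonFiniteError
from .geometry import ScanGeometry

__all__ = ["MarConfig", "segment_metal", "compute_trace", "apply_restriction"]

#: Relative floor on forward-projected metal-only values below which a bin is
#: not considered metal-affected; guards against interpolation-footprint
#: rounding while keeping "any positive contribution" semantics.
DEFAULT_TRACE_EPS_REL = 1e-9


@dataclass(frozen=True)
class MarConfig:
    """Tunables of the MAR reconstruction.

    Parameters
    ----------
    beta:
        Gradient-descent step size (dimensionless).  Default 1.  If a step
        would increase the objective it is retried with the step halved, up
        to ``max_halvings`` times.
    n_iterations:
        Fixed iteration count; no tolerance-based early exit.  Default 500.
    seg_fraction:
        Fraction of the raw-image maximum used as the metal segmentation
        threshold.  Default 1/3.
    trace_eps:
        Absolute threshold on forward-projected metal-only values for
        flagging a sinogram bin as metal-affected.  ``None`` (default)
        resolves at trace time to ``DEFAULT_TRACE_EPS_REL`` times the
        projection maximum.
    max_halvings:
        Step-halving budget per iteration before accepting an ascent step
        and raising the divergence flag.
    """

    beta: float = 1.0
    n_iterations: int = 500
    seg_fraction: float = 1.0 / 3.0
    trace_eps: float | None = None
    max_halvings: int = 20

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if not 0.0 < self.seg_fraction < 1.0:
            raise ValueError(f"seg_fraction must be in (0, 1), got {self.seg_fraction}")
        if self.trace_eps is not None and self.trace_eps < 0:
            raise ValueError(f"trace_eps must be >= 0, got {self.trace_eps}")
        if self.max_halvings < 0:
            raise ValueError(f"max_halvings must be >= 0, got {self.max_halvings}")


def segment_metal(raw: np.ndarray, seg_fraction: float = 1.0 / 3.0) -> np.ndarray:
    """Threshold a raw FBP image into a metal-only image.

    The threshold is ``seg_fraction * max(raw)``; pixels below it are zeroed,
    pixels at or above it are kept unchanged (ties kept).  An image with a
    non-positive maximum yields an all-zero (empty-metal) result.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(raw)):
        raise NonFiniteError("raw image contains non-finite values")
    if not 0.0 < seg_fraction < 1.0:
        raise ValueError(f"seg_fraction must be in (0, 1), got {seg_fraction}")
    threshold = seg_fraction * raw.max()
    if threshold <= 0.0:
        return np.zeros_like(raw)
    out = raw.copy()
    out[out < threshold] = 0.0
    return out


def compute_trace(
    metal_only: np.ndarray,
    geom: ScanGeometry,
    trace_eps: float | None = None,
) -> np.ndarray:
    """Boolean mask of metal-affected sinogram entries (index set of ``P_M``).

    Forward projects the metal-only image; entry (v, b) is flagged iff its
    projected value exceeds ``trace_eps``.  With the default ``trace_eps``
    this means "any positive contribution" up to rounding.
    """
    proj = forward_project(metal_only, geom)
    if trace_eps is None:
        trace_eps = DEFAULT_TRACE_EPS_REL * max(proj.max(), 0.0)
    mask = proj > trace_eps
    mask.flags.writeable = False
    return mask


def apply_restriction(sino: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Restriction operator ``D``: keep flagged entries, zero the rest.

    Shape-preserving so the restricted gradient can be subtracted from the
    full sinogram directly.  Idempotent and linear.
    """
    sino = np.asarray(sino, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if sino.shape != mask.shape:
        raise GeometryError(
            f"sinogram shape {sino.shape} does not match mask shape {mask.shape}"
        )
    return np.where(mask, sino, 0.0)
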