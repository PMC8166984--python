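"""Projection-domain MAR by penalizing negative FBP pixels.

The objective is the squared L2 norm of the negative part of the FBP
reconstruction,

    F(P) = || min(0, A P) ||_2^2,

where ``A`` is the (linear) FBP operator and ``P`` the sinogram.  There is
no data-fidelity term: the measured values are trusted everywhere except on
the metal trace, and only the metal-affected entries ``P_M`` are free
variables.  ``min(0, .)`` is not differentiable at zero; the subgradient

    grad F = 2 A^T min(0, A P)

(zero taken at pixels exactly at zero) drives a restricted gradient descent

    P_M <- P_M - beta * D [ 2 A^T min(0, A P) ],

with ``D`` the restriction to the metal trace.  Entries off the trace are
never touched, so they stay bit-identical to the measurement.  After the
fixed iteration budget the final image is one more FBP of the estimated
sinogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ct_core import fbp, fbp_adjoint
from .errors import NonFiniteError
from .geometry import ScanGeometry
from .metal_trace import MarConfig, apply_restriction, compute_trace, segment_metal

__all__ = [
    "MarResult",
    "negative_part",
    "objective",
    "subgradient",
    "clamp_negatives",
    "run_mar",
    "reconstruct_mar",
]

logger = logging.getLogger(__name__)


@dataclass
class MarResult:
    """Outcome of a restricted-gradient-descent MAR run.

    Attributes
    ----------
    final_sinogram:
        Measured sinogram with converged metal-affected entries.
    final_image:
        FBP reconstruction of ``final_sinogram``.
    objective_history:
        ``F`` at iterate 0 through ``n_iterations`` (length K+1).
    step_sizes:
        Step size actually used at each of the K iterations (after any
        halving), length ``n_iterations``.
    mask:
        Boolean metal-trace mask that restricted the updates.
    empty_mask:
        True when no sinogram entry was flagged; the run is then a no-op.
    diverged:
        True if some accepted step increased the objective after the
        halving budget was exhausted.
    """

    final_sinogram: np.ndarray
    final_image: np.ndarray
    objective_history: np.ndarray
    step_sizes: np.ndarray
    mask: np.ndarray
    empty_mask: bool = False
    diverged: bool = False
    warnings: list[str] = field(default_factory=list)


def _check_finite(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise NonFiniteError("image contains non-finite values")
    return img


def negative_part(img: np.ndarray) -> np.ndarray:
    """Elementwise ``min(0, x)``: keep negative pixels, zero the rest."""
    return np.minimum(0.0, _check_finite(img))


def clamp_negatives(img: np.ndarray) -> np.ndarray:
    """Elementwise ``max(0, x)`` — the naive comparator that zeroes negatives.

    This is *not* equivalent to the iterative algorithm; demonstrating the
    difference is the point of keeping it around.
    """
    return np.maximum(0.0, _check_finite(img))


def objective(img: np.ndarray) -> float:
    """Squared L2 norm of the image's negative pixels; zero iff img >= 0."""
    y = negative_part(img)
    return float(np.dot(y.ravel(), y.ravel()))


def subgradient(sino: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    """Subgradient ``2 A^T min(0, A P)`` of the objective at ``P``.

    Vanishes wherever the FBP image is nonnegative, so any such sinogram is
    a fixed point of the descent.
    """
    return 2.0 * fbp_adjoint(negative_part(fbp(sino, geom)), geom)


def run_mar(
    p0: np.ndarray,
    geom: ScanGeometry,
    cfg: MarConfig | None = None,
    mask: np.ndarray | None = None,
) -> MarResult:
    """Minimize the negative-pixel energy over the metal-affected projections.

    Parameters
    ----------
    p0:
        Measured sinogram; initializes the iterate (metal-affected entries
        start from their measured values — nothing is removed or inpainted).
    geom:
        Scan geometry shared by sinogram and image grid.
    cfg:
        Step size, iteration count, segmentation fraction and trace
        threshold; defaults follow :class:`~negmar.metal_trace.MarConfig`.
    mask:
        Precomputed metal-trace mask.  When omitted it is derived from
        ``p0`` via segment + forward-project (the mask is computed once and
        kept fixed across iterations).

    Notes
    -----
    Each iteration costs one FBP (shared by objective and gradient) and one
    adjoint application.  If a step would increase ``F`` it is retried with
    the step halved, up to ``cfg.max_halvings`` times; exhausting the budget
    accepts the step and sets the ``diverged`` flag.  An empty mask returns
    the raw reconstruction unchanged with ``empty_mask`` set.
    """
    cfg = cfg or MarConfig()
    p = geom.check_sinogram(p0).copy()

    if mask is None:
        raw = fbp(p, geom)
        metal_only = segment_metal(raw, cfg.seg_fraction)
        mask = compute_trace(metal_only, geom, cfg.trace_eps)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != geom.sinogram_shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match geometry "
                f"{geom.sinogram_shape}"
            )

    result_warnings: list[str] = []
    if not mask.any():
        msg = "metal trace is empty; returning the raw FBP reconstruction unchanged"
        warnings.warn(msg, stacklevel=2)
        result_warnings.append(msg)
        image = fbp(p, geom)
        f0 = objective(image)
        k = cfg.n_iterations
        return MarResult(
            final_sinogram=p,
            final_image=image,
            objective_history=np.full(k + 1, f0),
            step_sizes=np.zeros(k),
            mask=mask,
            empty_mask=True,
            warnings=result_warnings,
        )

    history = np.empty(cfg.n_iterations + 1)
    steps = np.empty(cfg.n_iterations)
    beta = cfg.beta
    diverged = False

    image = fbp(p, geom)
    f_cur = objective(image)
    history[0] = f_cur

    for k in range(cfg.n_iterations):
        grad = 2.0 * fbp_adjoint(negative_part(image), geom)
        step = apply_restriction(grad, mask)
        halvings = 0
        while True:
            p_new = p - beta * step
            image_new = fbp(p_new, geom)
            f_new = objective(image_new)
            if f_new <= f_cur or halvings >= cfg.max_halvings:
                break
            beta *= 0.5
            halvings += 1
            logger.info("iteration %d: objective rose, halving step to %g", k, beta)
        if f_new > f_cur:
            diverged = True
        p, image, f_cur = p_new, image_new, f_new
        history[k + 1] = f_cur
        steps[k] = beta
        logger.info("iteration %d: F = %.6g (beta = %g)", k + 1, f_cur, beta)

    if diverged:
        msg = "objective increased after exhausting the step-halving budget"
        warnings.warn(msg, stacklevel=2)
        result_warnings.append(msg)

    return MarResult(
        final_sinogram=p,
        final_image=image,
        objective_history=history,
        step_sizes=steps,
        mask=mask,
        diverged=diverged,
        warnings=result_warnings,
    )


def reconstruct_mar(
    p0: np.ndarray, geom: ScanGeometry, cfg: MarConfig | None = None
) -> tuple[MarResult, np.ndarray]:
    """Full pipeline: raw FBP, metal trace, restricted descent.

    Returns the :class:`MarResult` together with the raw FBP image (useful
    for comparisons against the clamp-negatives baseline).
    """
    cfg = cfg or MarConfig()
    p0 = geom.check_sinogram(p0)
    raw = fbp(p0, geom)
    metal_only = segment_metal(raw, cfg.seg_fraction)
    mask = compute_trace(metal_only, geom, cfg.trace_eps)
    result = run_mar(p0, geom, cfg, mask=mask)
    return result, raw
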