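"""STAPLE label fusion: EM estimation of a voxelwise organ probability from
multiple binary rater (warped-atlas) segmentations.

The model treats each rater j as a binary channel with latent sensitivity
``p_j = P(D_j = 1 | T = 1)`` and specificity ``q_j = P(D_j = 0 | T = 0)``
conditionally independent given the hidden true segmentation T.  The E-step
computes the posterior foreground weight at voxel i,

    w_i = a_i / (a_i + b_i),
    a_i = pi * prod_j p_j^{D_ij} (1 - p_j)^{1 - D_ij},
    b_i = (1 - pi) * prod_j (1 - q_j)^{D_ij} q_j^{1 - D_ij},

and the M-step re-estimates (p_j, q_j) from the weights.  The prior ``pi``
is the mean rater foreground fraction over the computation region, which is
restricted to the bounding box of the union of masks dilated by one voxel
(w = 0 outside); STAPLE's estimates are sensitive to how much background the
region contains, so the restriction is explicit and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import FusionFailureError
from .imaging import BinaryMask, VolumeGrid, require_same_grid

__all__ = [
    "RaterPerformance",
    "ProbabilityMap",
    "staple",
    "threshold_probability",
]

_CLAMP = 1e-6  # keeps p, q away from {0, 1} so the EM never degenerates


@dataclass
class RaterPerformance:
    """Per-rater sensitivity p and specificity q estimated by the EM."""

    p: np.ndarray
    q: np.ndarray

    def to_dict(self) -> dict:
        return {"sensitivity": self.p.tolist(), "specificity": self.q.tolist()}


@dataclass
class ProbabilityMap:
    """Voxelwise posterior that a voxel lies inside the organ."""

    grid: VolumeGrid
    w: np.ndarray
    prior: float
    iterations_run: int

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.min() < 0 or self.w.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


def _union_bounding_box(union: np.ndarray, pad: int = 1):
    idx = np.argwhere(union)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, union.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def staple(
    masks: list,
    max_iter: int = 20,
    tol: float = 1e-6,
    init_p: float = 0.9,
    init_q: float = 0.9,
    restrict_to_union_box: bool = True,
) -> tuple:
    """Run binary STAPLE on >= 2 rater masks sharing one grid.

    Returns ``(ProbabilityMap, RaterPerformance)``.  Stops after ``max_iter``
    EM iterations (20 by default) or when ``max |delta w| < tol``.
    """
    if len(masks) < 2:
        raise ValueError("STAPLE needs at least two raters")
    grid = masks[0].grid
    for m in masks[1:]:
        require_same_grid(masks[0], m)

    full = np.stack([m.bool for m in masks])  # (J, *shape)
    union = full.any(axis=0)
    if not union.any():
        raise FusionFailureError("all rater masks are empty")
    if full.all():
        raise FusionFailureError("all rater masks are full: no background evidence")

    box = _union_bounding_box(union) if restrict_to_union_box else tuple(
        slice(0, s) for s in grid.shape
    )
    D = full[(slice(None),) + box].reshape(len(masks), -1).astype(np.float64)
    J, M = D.shape

    pi = float(D.mean())
    p = np.full(J, init_p)
    q = np.full(J, init_q)
    w = np.full(M, pi)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # E-step
        log_a = np.log(pi) + (
            D.T @ np.log(p) + (1.0 - D).T @ np.log1p(-p)
        )
        log_b = np.log1p(-pi) + (
            D.T @ np.log1p(-q) + (1.0 - D).T @ np.log(q)
        )
        mx = np.maximum(log_a, log_b)
        a = np.exp(log_a - mx)
        b = np.exp(log_b - mx)
        w_new = a / (a + b)
        delta = float(np.abs(w_new - w).max())
        w = w_new
        # M-step
        sw = w.sum()
        swc = (1.0 - w).sum()
        p = np.clip((D @ w) / sw if sw > 0 else p, _CLAMP, 1 - _CLAMP)
        q = np.clip(
            ((1.0 - D) @ (1.0 - w)) / swc if swc > 0 else q, _CLAMP, 1 - _CLAMP
        )
        if delta < tol:
            break

    w_full = np.zeros(grid.shape)
    w_full[box] = w.reshape(tuple(s.stop - s.start for s in box))
    return (
        ProbabilityMap(grid, w_full, pi, iterations),
        RaterPerformance(p, q),
    )


def threshold_probability(
    prob: ProbabilityMap,
    threshold: float = 0.7,
    keep_largest_component: bool = True,
    organ_label: str = "",
) -> BinaryMask:
    """Threshold the posterior (inclusive, ``w >= threshold``) into the
    refinement seed, keeping the largest 26-connected component."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    fg = prob.w >= threshold
    if not fg.any():
        raise FusionFailureError(
            f"organ '{organ_label}' empty at probability threshold {threshold}; "
            "needs manual segmentation"
        )
    if keep_largest_component:
        labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
            fg = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(prob.grid, fg.astype(np.uint8), organ_label)
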