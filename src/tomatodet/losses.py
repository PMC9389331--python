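"""Training objective: penalty-reduced focal heatmap loss plus L1 heads.

The heatmap loss is a focal cross-entropy in which cells inside a
ground-truth Gaussian (Y close to 1) are penalized less than far
background via the ``(1 - Y)^beta`` factor, and easy predictions are
down-weighted by ``(1 - p)^alpha``.  Offset and radius heads are plain L1
losses evaluated only at keypoint cells.  The total detection loss is
``L_hm + lambda_off * L_off + lambda_r * L_r`` with the defaults
``lambda_off = 1`` and ``lambda_r = 0.1``; the focal exponents default to
``alpha = 2`` and ``beta = 4``.

All functions accept either numpy arrays (returning a float) or autograd
tensors (returning a scalar tensor suitable for ``backward``), on
single-image ``(C, H, W)`` or batched ``(N, C, H, W)`` maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "LossBreakdown",
    "heatmap_focal_loss",
    "offset_loss",
    "radius_loss",
    "total_loss",
    "compute_losses",
]

# predictions are clamped away from {0, 1} before logs
EPS = 1e-4


@dataclass
class LossBreakdown:
    """Loss components for one batch, plus the weights combining them."""

    L_hm: float
    L_off: float
    L_r: float
    lambda_off: float = 1.0
    lambda_r: float = 0.1
    alpha_focal: float = 2.0
    beta_focal: float = 4.0

    @property
    def L_det(self) -> float:
        return self.L_hm + self.lambda_off * self.L_off + self.lambda_r * self.L_r


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _batched(t: Tensor) -> Tensor:
    return t.reshape(1, *t.shape) if t.ndim == 3 else t


def heatmap_focal_loss(y_hat, y, alpha_focal: float = 2.0, beta_focal: float = 4.0):
    """Penalty-reduced focal loss between predicted and target heatmaps.

    ``-(1/N) * sum[ (1-p)^alpha log p ]`` over Y=1 cells plus
    ``-(1/N) * sum[ (1-Y)^beta p^alpha log(1-p) ]`` over the rest, where N
    is the per-image keypoint count (divisor 1 for images with no
    keypoints), averaged over the batch.
    """
    y_hat_t, was_tensor = _as_tensor(y_hat)
    y_hat_t = _batched(y_hat_t)
    y = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=y_hat_t.data.dtype)
    if y.ndim == 3:
        y = y[None]
    pos_mask = (y == 1.0).astype(y.dtype)
    neg_mask = 1.0 - pos_mask
    n_pos = np.maximum(pos_mask.sum(axis=(1, 2, 3)), 1.0)

    p = y_hat_t.clamp(EPS, 1.0 - EPS)
    pos_term = ((1.0 - p) ** alpha_focal) * p.log() * Tensor(pos_mask)
    neg_term = (
        Tensor(((1.0 - y) ** beta_focal) * neg_mask) * (p**alpha_focal) * (1.0 - p).log()
    )
    per_image = (pos_term + neg_term).sum(axis=(1, 2, 3)) * Tensor(-1.0 / n_pos)
    out = per_image.mean()
    return out if was_tensor else out.item()


def _masked_l1(pred, target, keypoint_mask):
    pred_t, was_tensor = _as_tensor(pred)
    pred_t = _batched(pred_t)
    target = np.asarray(
        target.data if isinstance(target, Tensor) else target, dtype=pred_t.data.dtype
    )
    if target.ndim == 3:
        target = target[None]
    mask = np.asarray(keypoint_mask, dtype=pred_t.data.dtype)
    if mask.ndim == 2:
        mask = mask[None]
    n = mask.sum()
    if n == 0:
        return Tensor(0.0) if was_tensor else 0.0
    mask_b = mask[:, None]  # broadcast over the channel axis
    out = ((pred_t - Tensor(target)).abs() * Tensor(mask_b)).sum() * (1.0 / n)
    return out if was_tensor else out.item()


def offset_loss(o_hat, o, keypoint_mask):
    """Mean L1 distance of predicted to true sub-cell offsets at keypoints.

    Both offset components contribute; the divisor is the number of
    keypoints N (an empty mask gives 0).
    """
    return _masked_l1(o_hat, o, keypoint_mask)


def radius_loss(r_hat, r_targets, keypoint_mask):
    """Mean absolute radius error over the N keypoint cells."""
    return _masked_l1(r_hat, r_targets, keypoint_mask)


def total_loss(b: LossBreakdown) -> float:
    """Weighted sum ``L_hm + lambda_off * L_off + lambda_r * L_r``."""
    return b.L_det


def compute_losses(
    y_hat,
    o_hat,
    r_hat,
    y,
    o,
    r_targets,
    keypoint_mask,
    lambda_off: float = 1.0,
    lambda_r: float = 0.1,
    alpha_focal: float = 2.0,
    beta_focal: float = 4.0,
):
    """All loss components for one batch.

    Returns ``(loss_tensor_or_float, LossBreakdown)``: the first element is
    the differentiable total when tensor inputs were supplied, else the
    float total; the breakdown always carries plain floats.
    """
    l_hm = heatmap_focal_loss(y_hat, y, alpha_focal, beta_focal)
    l_off = offset_loss(o_hat, o, keypoint_mask)
    l_r = radius_loss(r_hat, r_targets, keypoint_mask)
    if isinstance(l_hm, Tensor):
        total = l_hm + lambda_off * l_off + lambda_r * l_r
        breakdown = LossBreakdown(
            l_hm.item(),
            l_off.item() if isinstance(l_off, Tensor) else float(l_off),
            l_r.item() if isinstance(l_r, Tensor) else float(l_r),
            lambda_off,
            lambda_r,
            alpha_focal,
            beta_focal,
        )
        return total, breakdown
    breakdown = LossBreakdown(l_hm, l_off, l_r, lambda_off, lambda_r, alpha_focal, beta_focal)
    return breakdown.L_det, breakdown
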