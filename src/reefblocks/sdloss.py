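"""Scale-aware dynamic box regression loss.

A CIoU-style loss whose two penalty weights vary linearly with the
normalized ground-truth area beta = (w_gt * h_gt) / (W_image * H_image):

    L = (1 - IoU) + w_d * R_DIoU + w_s * R_CIoU
    w_d = 1 + delta - beta        (center-distance penalty weight)
    w_s = 1 - delta + beta        (aspect/shape penalty weight)

so small targets emphasize the stable distance term and large targets the
fine-grained shape term; w_d + w_s == 2 identically.  With beta == delta the
loss reduces to the standard CIoU loss.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import InputError
from .nn import Tensor, functional as F

__all__ = ["SDLossTerms", "scale_weights", "sd_loss", "sd_loss_tensor"]

_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class SDLossTerms:
    iou: float
    r_diou: float
    r_ciou: float
    w_d: float
    w_s: float
    total: float


def scale_weights(beta: float, delta: float) -> tuple[float, float]:
    """Dynamic penalty weights (w_d, w_s); requires beta in [0,1], delta in [0,1]."""
    if not 0.0 <= beta <= 1.0:
        raise InputError(f"beta must be in [0,1], got {beta}")
    if not 0.0 <= delta <= 1.0:
        raise InputError(f"delta must be in [0,1], got {delta}")
    return 1.0 + delta - beta, 1.0 - delta + beta


def _ciou_terms(pred: np.ndarray, gt: np.ndarray):
    """IoU, normalized center-distance penalty and aspect penalty for
    (x1,y1,x2,y2) boxes (vectorized over leading axes)."""
    px1, py1, px2, py2 = (pred[..., i] for i in range(4))
    gx1, gy1, gx2, gy2 = (gt[..., i] for i in range(4))
    pw, ph = px2 - px1, py2 - py1
    gw, gh = gx2 - gx1, gy2 - gy1
    ix = np.clip(np.minimum(px2, gx2) - np.maximum(px1, gx1), 0, None)
    iy = np.clip(np.minimum(py2, gy2) - np.maximum(py1, gy1), 0, None)
    inter = ix * iy
    union = pw * ph + gw * gh - inter
    iou = inter / (union + _EPS)
    # enclosing box diagonal
    cw = np.maximum(px2, gx2) - np.minimum(px1, gx1)
    ch = np.maximum(py2, gy2) - np.minimum(py1, gy1)
    c2 = cw**2 + ch**2 + _EPS
    d2 = ((px1 + px2 - gx1 - gx2) ** 2 + (py1 + py2 - gy1 - gy2) ** 2) / 4.0
    r_diou = d2 / c2
    v = (4 / np.pi**2) * (np.arctan(gw / (gh + _EPS))
                          - np.arctan(pw / (ph + _EPS))) ** 2
    alpha = v / (1.0 - iou + v + _EPS)
    return iou, r_diou, alpha * v


def sd_loss(pred_box, gt_box, image_size, delta: float = 0.5) -> SDLossTerms:
    """Scalar reference implementation on one (pred, gt) pair of
    (x1, y1, x2, y2) boxes in absolute pixels."""
    pred = np.asarray(pred_box, dtype=float)
    gt = np.asarray(gt_box, dtype=float)
    w_img, h_img = (image_size, image_size) if np.isscalar(image_size) else image_size
    gw, gh = gt[2] - gt[0], gt[3] - gt[1]
    if gw <= 0 or gh <= 0:
        raise InputError("ground-truth box must have positive area")
    if w_img <= 0 or h_img <= 0:
        raise InputError("image size must be positive")
    beta = float(np.clip((gw * gh) / (w_img * h_img), 0.0, 1.0))
    w_d, w_s = scale_weights(beta, delta)
    iou, r_diou, r_ciou = _ciou_terms(pred, gt)
    total = (1.0 - iou) + w_d * r_diou + w_s * r_ciou
    return SDLossTerms(iou=float(iou), r_diou=float(r_diou),
                       r_ciou=float(r_ciou), w_d=w_d, w_s=w_s,
                       total=float(total))


def sd_loss_tensor(pred: Tensor, gt: np.ndarray, image_size,
                   delta: float = 0.5, dynamic: bool = True) -> Tensor:
    """Differentiable batch loss (mean-reduced) for training.

    pred: Tensor (N, 4) predicted (x1,y1,x2,y2); gt: array (N, 4).
    The alpha balance inside the aspect term is treated as a constant, as in
    the reference CIoU formulation.  With ``dynamic=False`` both penalty
    weights are fixed at 1 (the plain CIoU loss).
    """
    gt = np.asarray(gt, dtype=np.float32)
    if gt.size == 0:
        return Tensor(0.0)
    w_img, h_img = (image_size, image_size) if np.isscalar(image_size) else image_size
    gw, gh = gt[:, 2] - gt[:, 0], gt[:, 3] - gt[:, 1]
    if np.any(gw <= 0) or np.any(gh <= 0):
        raise InputError("ground-truth boxes must have positive area")
    if dynamic:
        beta = np.clip((gw * gh) / (w_img * h_img), 0.0, 1.0)
        w_d = (1.0 + delta - beta).astype(np.float32)
        w_s = (1.0 - delta + beta).astype(np.float32)
    else:
        w_d = np.ones_like(gw, dtype=np.float32)
        w_s = np.ones_like(gw, dtype=np.float32)

    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    gx1, gy1, gx2, gy2 = (Tensor(gt[:, i]) for i in range(4))
    pw, ph = px2 - px1, py2 - py1

    def _min(a, b):
        return (a + b - abs_diff(a, b)) * 0.5

    def _max(a, b):
        return (a + b + abs_diff(a, b)) * 0.5

    def abs_diff(a, b):
        return F.abs_(a - b)

    ix = F.relu(_min(px2, gx2) - _max(px1, gx1))
    iy = F.relu(_min(py2, gy2) - _max(py1, gy1))
    inter = ix * iy
    union = pw * ph + Tensor((gw * gh).astype(np.float32)) - inter
    iou = inter / (union + _EPS)
    cw = _max(px2, gx2) - _min(px1, gx1)
    ch = _max(py2, gy2) - _min(py1, gy1)
    c2 = cw * cw + ch * ch + _EPS
    d2 = ((px1 + px2 - gx1 - gx2) ** 2 + (py1 + py2 - gy1 - gy2) ** 2) * 0.25
    r_diou = d2 / c2
    # aspect term: v with the arctan formulation; alpha detached
    atan_p = arctan(pw / (ph + _EPS))
    atan_g = np.arctan(gw / (gh + _EPS)).astype(np.float32)
    v = (Tensor(atan_g) - atan_p) ** 2 * (4.0 / np.pi**2)
    alpha_const = v.data / (1.0 - iou.data + v.data + _EPS)
    r_ciou = v * Tensor(alpha_const)
    loss = (1.0 - iou) + Tensor(w_d) * r_diou + Tensor(w_s) * r_ciou
    return loss.mean()


def arctan(x: Tensor) -> Tensor:
    out_data = np.arctan(x.data)

    def bwd(g):
        if x.requires_grad:
            x._accum(g / (1.0 + x.data**2))

    return Tensor._make(out_data, (x,), bwd)
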