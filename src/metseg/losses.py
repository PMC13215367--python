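"""Segmentation losses: Dice, cross-entropy and the patch-based LRP focal term.

The total training loss is

    L = L_Dice + (1 - w) * L_CE + w * L_LRP

where ``L_LRP`` is a focal loss over non-overlapping 8x8x8-voxel patches:
each patch gets a binary label ``y_l`` (1 iff it contains any lesion voxel)
and a predicted presence probability ``q_l`` (patch-wise max of the voxel
foreground probabilities by default), and the per-patch term is the two-sided
focal cross-entropy

    -[ y (1 - q)^g log q  +  (1 - y) q^g log(1 - q) ]

with focusing parameter ``g`` (gamma, default 0.5).  The one-sided variant
(positive patches only) is available via ``one_sided=True``.  The focal
modulation concentrates gradient on hard positive patches — volumes are
dominated by easy lesion-free background patches, and small (<3 mm) lesions
occupy only a handful of voxels in one or two patches.

All losses accept either plain numpy arrays or autodiff Tensors and return a
scalar :class:`~metseg.autodiff.Tensor`; use ``float(...)`` for the value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor

__all__ = ["LossConfig", "dice_loss", "ce_loss", "patch_labels",
           "patch_probs", "lrp_loss", "composite_loss"]

P_EPS = 1e-7          # probability squash before logs


def _squash(p):
    """Affine map [0, 1] -> [eps, 1-eps] applied before logarithms.

    Unlike hard clamping, the gradient flows everywhere — a voxel whose
    probability has saturated to exactly 0 or 1 (float32 softmax) can still
    be pulled back.  Exact at p = 0.5.
    """
    return p * (1.0 - 2.0 * P_EPS) + P_EPS


@dataclass
class LossConfig:
    w: float = 0.4               # LRP mixing weight in [0, 1]
    gamma: float = 0.5           # focal focusing parameter
    patch_size: int = 8          # voxels per patch axis
    smooth: float = 1e-5         # Dice stabiliser
    aggregation: str = "max"     # patch prob pooling: "max" | "noisy_or"
    one_sided: bool = False      # literal positive-only focal form

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.aggregation not in ("max", "noisy_or"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


def _check_same_shape(a, b):
    if tuple(a.shape) != tuple(b.shape):
        raise ValueError(f"shape mismatch: {tuple(a.shape)} vs {tuple(b.shape)}")


def dice_loss(pred, gt, smooth: float = 1e-5) -> Tensor:
    """Soft Dice loss: 1 - (2*sum(p*g) + eps) / (sum p + sum g + eps)."""
    pred, gt = astensor(pred), astensor(gt)
    _check_same_shape(pred, gt)
    inter = (pred * gt).sum()
    denom = pred.sum() + gt.sum() + smooth
    return 1.0 - (2.0 * inter + smooth) / denom


def ce_loss(pred, gt) -> Tensor:
    """Binary cross-entropy: mean over voxels of -log p(correct class).

    ``pred`` is the per-voxel foreground probability; background probability
    is its complement (two-class softmax output).
    """
    pred, gt = astensor(pred), astensor(gt)
    _check_same_shape(pred, gt)
    p_correct = pred * gt + (1.0 - pred) * (1.0 - gt)
    return -(_squash(p_correct).log()).mean()


def _patch_view_np(arr: np.ndarray, ps: int) -> np.ndarray:
    """(D,H,W) -> (n_patches, ps^3) in raster order over the patch grid."""
    D, H, W = arr.shape
    if D % ps or H % ps or W % ps:
        raise ValueError(f"patch size {ps} does not divide shape {arr.shape}")
    v = arr.reshape(D // ps, ps, H // ps, ps, W // ps, ps)
    return v.transpose(0, 2, 4, 1, 3, 5).reshape(-1, ps ** 3)


def patch_labels(gt, patch_size: int = 8) -> np.ndarray:
    """Binary patch labels: 1 iff the patch contains any lesion voxel."""
    gt = np.asarray(gt.data if isinstance(gt, Tensor) else gt)
    return (_patch_view_np(gt, patch_size).max(axis=1) > 0).astype(np.float64)


def patch_probs(pred, patch_size: int = 8,
                aggregation: str = "max") -> Tensor:
    """Patch presence probabilities q_l, differentiable w.r.t. ``pred``.

    "max" takes the strongest voxel per patch; "noisy_or" uses
    1 - prod(1 - p), the probability at least one voxel fires under
    independence.
    """
    pred = astensor(pred)
    D, H, W = pred.shape
    ps = patch_size
    if D % ps or H % ps or W % ps:
        raise ValueError(f"patch size {ps} does not divide shape {pred.shape}")
    blocks = pred.reshape(D // ps, ps, H // ps, ps, W // ps, ps)
    blocks = blocks.transpose(0, 2, 4, 1, 3, 5).reshape(-1, ps ** 3)
    if aggregation == "max":
        return blocks.max(axis=1)
    if aggregation == "noisy_or":
        log_miss = _squash(1.0 - blocks).log().sum(axis=1)
        return 1.0 - log_miss.exp()
    raise ValueError(f"unknown aggregation {aggregation!r}")


def lrp_loss(y, q, gamma: float = 0.5, one_sided: bool = False) -> Tensor:
    """Patch-level focal loss, mean over patches.

    Two-sided by default; ``one_sided=True`` keeps only the positive-patch
    term -y (1-q)^gamma log q.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    y = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=np.float64)
    q = astensor(q)
    _check_same_shape(y, q)
    qc = _squash(q)
    pos = Tensor(y) * (1.0 - qc) ** gamma * qc.log()
    if one_sided:
        return -(pos.mean())
    neg = Tensor(1.0 - y) * qc ** gamma * (1.0 - qc).log()
    return -((pos + neg).mean())


def composite_loss(pred, gt, config: LossConfig | None = None) -> Tensor:
    """L_Dice + (1 - w) L_CE + w L_LRP on one volume."""
    config = config or LossConfig()
    pred, gt = astensor(pred), astensor(gt)
    _check_same_shape(pred, gt)
    total = dice_loss(pred, gt, config.smooth) + (1.0 - config.w) * ce_loss(pred, gt)
    if config.w > 0:
        y = patch_labels(gt, config.patch_size)
        q = patch_probs(pred, config.patch_size, config.aggregation)
        total = total + config.w * lrp_loss(y, q, config.gamma,
                                            config.one_sided)
    return total
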