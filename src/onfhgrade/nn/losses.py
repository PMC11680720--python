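"""Loss functions and supervision targets for the dual-supervised U-Net.

Three independent supervision signals are combined:

* main: per-pixel binary cross-entropy plus soft Dice loss on the
  full-resolution probability map;
* geometric: mean absolute error between a predicted signed distance map and
  the signed Euclidean distance transform of the true mask boundary, with
  distances clipped to +/-``SDT_CLIP`` pixels;
* pixel-level: deep supervision — mean cross-entropy of the downsampled
  auxiliary probability maps at each coarser decoder resolution against
  block-majority-downsampled ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, distance_transform_edt

SDT_CLIP = 20.0
_EPS = 1e-7
_DICE_SMOOTH = 1.0


def signed_distance_map(mask: np.ndarray, clip: float = SDT_CLIP) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary, clipped to +/-``clip``.

    The boundary is the set of mask pixels with at least one 4-neighbor
    outside the mask (image-edge mask pixels count as boundary). Distances
    are zero exactly on boundary pixels, negative strictly inside, positive
    outside. An empty mask yields a map of +``clip`` everywhere.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.full(mask.shape, clip, dtype=np.float32)
    interior = binary_erosion(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
                              border_value=0)
    boundary = mask & ~interior
    dist = distance_transform_edt(~boundary)
    sdt = np.where(mask, -dist, dist)
    return np.clip(sdt, -clip, clip).astype(np.float32)


def downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Block-majority downsampling of a binary mask by an integer factor."""
    h, w = mask.shape
    blocks = mask.reshape(h // factor, factor, w // factor, factor)
    return blocks.mean(axis=(1, 3)) >= 0.5


def binary_cross_entropy(p: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean BCE over all pixels; returns (value, d(value)/d(logit) given p=sigmoid(z)).

    The gradient is expressed directly with respect to the pre-sigmoid logit,
    where it takes the numerically exact form (p - t)/n.
    """
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    t = t.astype(p.dtype)
    value = float(-np.mean(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)))
    grad_logit = (p - t) / p.size
    return value, grad_logit.astype(np.float32)


def dice_loss(p: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Soft Dice loss averaged per image; returns (value, d/d(p)).

    ``p`` and ``t`` are (N, H, W). The smoothing constant keeps the empty
    mask / empty prediction case well-defined with zero loss.
    """
    t = t.astype(p.dtype)
    axes = tuple(range(1, p.ndim))
    inter = (p * t).sum(axis=axes)
    sums = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (2.0 * inter + _DICE_SMOOTH) / (sums + _DICE_SMOOTH)
    value = float(np.mean(1.0 - dice))
    # d(1-dice_i)/dp = -(2 t (sums+s) - (2 inter + s)) / (sums+s)^2, averaged over images
    denom = (sums + _DICE_SMOOTH) ** 2
    grad = -(2.0 * t * (sums + _DICE_SMOOTH)[..., None, None] - (2.0 * inter + _DICE_SMOOTH)[..., None, None]) / denom[..., None, None]
    return value, (grad / p.shape[0]).astype(np.float32)


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error; returns (value, d/d(pred))."""
    diff = pred - target
    value = float(np.mean(np.abs(diff)))
    return value, (np.sign(diff) / pred.size).astype(np.float32)


@dataclass
class LossComponents:
    """Breakdown of the composite training loss."""

    total: float
    main: float
    main_bce: float
    main_dice: float
    geometric: float
    pixel: float

    def as_dict(self) -> dict[str, float]:
        return {
            "total": self.total,
            "main": self.main,
            "main_bce": self.main_bce,
            "main_dice": self.main_dice,
            "geometric": self.geometric,
            "pixel": self.pixel,
        }


def composite_components(
    main_prob: np.ndarray,
    geo_pred: np.ndarray,
    ds_probs: list[np.ndarray],
    truth: np.ndarray,
    weights: tuple[float, float, float],
    *,
    with_grads: bool = False,
):
    """Weighted composite loss over the three supervision paths.

    ``main_prob`` and ``geo_pred`` are (N, H, W); ``ds_probs`` holds the
    deep-supervision probability maps at successively halved resolutions;
    ``truth`` is the (N, H, W) boolean femoral-head mask. When
    ``with_grads`` is true, also returns gradients with respect to the main
    logits, the geometric prediction, and each deep-supervision logit map.
    """
    w_main, w_geo, w_pix = weights
    truth = np.asarray(truth, dtype=bool)

    bce_val, d_main_logit = binary_cross_entropy(main_prob, truth)
    dice_val, d_dice_p = dice_loss(main_prob, truth)

    sdt = np.stack([signed_distance_map(m) for m in truth])
    geo_val, d_geo = l1_loss(geo_pred, sdt)

    pix_vals = []
    d_ds = []
    for ds_p in ds_probs:
        factor = truth.shape[-1] // ds_p.shape[-1]
        t_small = np.stack([downsample_mask(m, factor) for m in truth])
        v, g = binary_cross_entropy(ds_p, t_small)
        pix_vals.append(v)
        d_ds.append(g)
    pix_val = float(np.mean(pix_vals)) if pix_vals else 0.0

    comps = LossComponents(
        total=w_main * (bce_val + dice_val) + w_geo * geo_val + w_pix * pix_val,
        main=bce_val + dice_val,
        main_bce=bce_val,
        main_dice=dice_val,
        geometric=geo_val,
        pixel=pix_val,
    )
    if not with_grads:
        return comps

    # Chain rule through the sigmoid for the Dice term; the BCE gradient is
    # already expressed with respect to the logit.
    sig_deriv = main_prob * (1.0 - main_prob)
    g_main = (w_main * (d_main_logit + d_dice_p * sig_deriv)).astype(np.float32)
    g_geo = (w_geo * d_geo).astype(np.float32)
    n_levels = max(len(ds_probs), 1)
    g_ds = [(w_pix * g / n_levels).astype(np.float32) for g in d_ds]
    return comps, g_main, g_geo, g_ds
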