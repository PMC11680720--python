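"""Necrotic-region extraction by adaptive (Otsu) thresholding.

Within the segmented femoral head, the intensity histogram is assumed
bimodal: bright normal marrow versus darker necrotic tissue on T1-weighted
images. The optimal cutoff maximizes the between-class variance over a
256-bin histogram of head-region pixels only; ties are broken toward the
lowest maximizing threshold for determinism. Necrosis polarity (below or
above the threshold) is configurable; "dark" is the T1 default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import remove_small_objects

from .datatypes import RegionMask, Slice, validate_mask
from .errors import DegenerateInputError, NoFemoralHeadError, ValidationError

__all__ = ["ThresholdResult", "adaptive_threshold", "compute_proportion"]

N_BINS = 256


@dataclass
class ThresholdResult:
    """Outcome of adaptive thresholding inside the femoral head."""

    threshold: float  # intensity cutoff in [0, 1]
    necrosis_mask: RegionMask
    between_class_variance: float  # at the selected threshold, intensity^2 units
    histogram: np.ndarray  # 256-bin counts of head-region intensities


def _otsu_from_histogram(hist: np.ndarray) -> tuple[int, float]:
    """Lowest bin index maximizing between-class variance; (index, variance).

    Candidate ``t`` assigns bins 0..t to the low class and t+1..255 to the
    high class; only splits with both classes non-empty are valid.
    """
    hist = hist.astype(np.float64)
    total = hist.sum()
    centers = (np.arange(hist.size) + 0.5) / hist.size
    w0 = np.cumsum(hist)
    w1 = total - w0
    mu0 = np.cumsum(hist * centers)
    mu_total = mu0[-1]
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise DegenerateInputError(
            "head-region intensities fall in a single histogram bin; no threshold separates them"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = mu0 / w0
        m1 = (mu_total - mu0) / w1
        bcv = w0 / total * w1 / total * (m0 - m1) ** 2
    bcv[~valid] = -np.inf
    t = int(np.argmax(bcv))  # argmax returns the first (lowest) maximizer
    return t, float(bcv[t])


def adaptive_threshold(
    slc: Slice,
    head_mask: RegionMask,
    polarity: str = "dark",
    min_component: int = 0,
) -> ThresholdResult:
    """Select the optimal intensity cutoff inside the femoral head.

    ``polarity="dark"`` flags pixels strictly below the threshold as necrotic
    (T1 appearance); ``"bright"`` flags pixels at or above it.
    ``min_component`` optionally removes necrotic components smaller than
    that pixel count (off by default).
    """
    head_mask = validate_mask(head_mask, name="head_mask")
    if head_mask.shape != slc.pixels.shape:
        raise ValidationError("head_mask must share the slice shape")
    if polarity not in ("dark", "bright"):
        raise ValidationError(f"polarity must be 'dark' or 'bright', got {polarity!r}")
    if not head_mask.any():
        raise NoFemoralHeadError("no femoral head found: head mask is empty")

    vals = slc.pixels[head_mask]
    if vals.max() == vals.min():
        raise DegenerateInputError("head region is constant: no intensity contrast to threshold")

    # Quantize so that bin q <= t corresponds exactly to intensity < (t+1)/256.
    q = np.minimum((vals * N_BINS).astype(np.int64), N_BINS - 1)
    hist = np.bincount(q, minlength=N_BINS)
    t, bcv = _otsu_from_histogram(hist)
    threshold = (t + 1) / N_BINS

    if polarity == "dark":
        necrosis = head_mask & (slc.pixels < threshold)
    else:
        necrosis = head_mask & (slc.pixels >= threshold)
    if min_component > 0:
        necrosis = remove_small_objects(necrosis, min_size=min_component)
    return ThresholdResult(
        threshold=float(threshold),
        necrosis_mask=necrosis,
        between_class_variance=bcv,
        histogram=hist,
    )


def compute_proportion(necrosis_mask: RegionMask, head_mask: RegionMask) -> float:
    """Necrotic share of the femoral head in percent, at pixel level."""
    necrosis_mask = validate_mask(necrosis_mask, name="necrosis_mask")
    head_mask = validate_mask(head_mask, name="head_mask")
    if necrosis_mask.shape != head_mask.shape:
        raise ValidationError("masks must share a shape")
    if not head_mask.any():
        raise NoFemoralHeadError("no femoral head found: head mask is empty")
    if (necrosis_mask & ~head_mask).any():
        raise ValidationError("necrosis_mask must be contained in head_mask")
    return float(100.0 * necrosis_mask.sum() / head_mask.sum())
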