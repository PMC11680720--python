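"""Synthetic axial-slice phantoms with known ground truth.

Each phantom emulates the appearance of one femoral head on an axial
T1-weighted slice: a bright elliptical head (fatty marrow), a darker
necrotic blob in its superior portion (early osteonecrotic lesions are
typically anterosuperior and hypointense on T1), a structured background
(smoothed random field plus a dark acetabular arc so that segmentation is
nontrivial), and additive Gaussian noise.  Because the lesion geometry is
rasterized, the ground-truth necrotic proportion is always recomputed from
the masks rather than taken from the requested fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .datatypes import RegionMask, Slice
from .errors import ValidationError

__all__ = ["PhantomSpec", "PhantomSample", "CohortRanges", "generate_phantom", "generate_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    ``lesion_fraction`` is the target necrotic share of head area in percent;
    the generator hits it by binary search on the lesion radius, so the
    rasterized proportion lands within one percentage point whenever the head
    covers at least a couple of thousand pixels.
    """

    image_size: int = 256
    head_center: tuple[float, float] = (128.0, 128.0)  # (row, col), px
    head_radii: tuple[float, float] = (60.0, 60.0)  # (r_row, r_col) semi-axes, px
    lesion_fraction: float = 20.0  # percent of head area
    head_intensity: float = 0.8
    lesion_intensity: float = 0.3
    background_texture_scale: float = 12.0  # smoothing length, px
    noise_sigma: float = 0.02
    seed: int = 0
    spacing_mm: float = 1.0  # recorded in the Slice, unused downstream

    def validate(self) -> None:
        if self.image_size < 16:
            raise ValidationError("image_size must be at least 16 pixels")
        if not (0.0 <= self.lesion_fraction <= 100.0):
            raise ValidationError(f"lesion_fraction must be in [0, 100], got {self.lesion_fraction}")
        if not (0.0 < self.head_intensity <= 1.0):
            raise ValidationError(f"head_intensity must be in (0, 1], got {self.head_intensity}")
        if not (0.0 <= self.lesion_intensity < 1.0):
            raise ValidationError(f"lesion_intensity must be in [0, 1), got {self.lesion_intensity}")
        if self.lesion_intensity >= self.head_intensity:
            raise ValidationError(
                "lesion_intensity must be below head_intensity "
                "(necrosis is hypointense on T1-weighted images)"
            )
        ry, rx = self.head_radii
        if ry <= 0 or rx <= 0:
            raise ValidationError(f"head_radii must be positive, got {self.head_radii}")
        cy, cx = self.head_center
        n = self.image_size
        if cy - ry < 0 or cy + ry > n - 1 or cx - rx < 0 or cx + rx > n - 1:
            raise ValidationError("head_center/head_radii: head ellipse must lie fully inside the image")
        if self.background_texture_scale <= 0:
            raise ValidationError("background_texture_scale must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")


@dataclass
class PhantomSample:
    """A generated slice with its ground-truth masks and necrotic proportion."""

    image: Slice
    head_mask: RegionMask
    necrosis_mask: RegionMask
    true_proportion: float  # percent, recounted from the rasterized masks
    spec: PhantomSpec


def _lesion_mask(head: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Superior lesion blob sized by binary search to hit the target area."""
    head_count = int(head.sum())
    target = spec.lesion_fraction / 100.0 * head_count
    if target < 0.5:
        return np.zeros_like(head)

    cy, cx = spec.head_center
    ry, rx = spec.head_radii
    # Seed point in the superior (low row index) portion of the head.
    ly, lx = cy - 0.45 * ry, cx
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    d2 = (yy - ly) ** 2 + (xx - lx) ** 2

    def area(radius: float) -> int:
        return int((head & (d2 <= radius * radius)).sum())

    lo, hi = 0.0, 2.0 * (ry + rx)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if area(mid) < target:
            lo = mid
        else:
            hi = mid
    # Pick whichever bracket end lands closer to the target pixel count.
    radius = lo if abs(area(lo) - target) <= abs(area(hi) - target) else hi
    return head & (d2 <= radius * radius)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one synthetic slice with ground-truth head and necrosis masks.

    Deterministic for a fixed spec: the same seed yields bit-identical
    pixels and masks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    cy, cx = spec.head_center
    ry, rx = spec.head_radii

    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    head = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    lesion = _lesion_mask(head, spec)

    # Background: smoothed random field, mid-gray with soft-tissue-like texture.
    field = gaussian_filter(rng.standard_normal((n, n)), spec.background_texture_scale)
    sd = field.std()
    if sd > 0:
        field /= sd
    img = 0.30 + 0.08 * field

    # Dark acetabular arc hugging the supero-lateral head boundary.
    r_ell = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    arc = (r_ell > 1.06) & (r_ell < 1.22) & (yy < cy + 0.3 * ry)
    img[arc] = 0.08

    img[head] = spec.head_intensity
    img[lesion] = spec.lesion_intensity

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(n, n))
    img = np.clip(img, 0.0, 1.0)

    head_count = int(head.sum())
    true_proportion = 100.0 * lesion.sum() / head_count if head_count else 0.0
    image = Slice(
        pixels=img,
        spacing=(spec.spacing_mm, spec.spacing_mm),
        source_id=f"phantom-{spec.seed}",
        source_format="array",
    )
    return PhantomSample(
        image=image,
        head_mask=head,
        necrosis_mask=lesion,
        true_proportion=float(true_proportion),
        spec=spec,
    )


@dataclass(frozen=True)
class CohortRanges:
    """Uniform sampling ranges for cohort generation, all (low, high) inclusive."""

    head_radius: tuple[float, float] = (45.0, 70.0)
    center_jitter: float = 15.0  # max |offset| of head center from image center, px
    lesion_fraction: tuple[float, float] = (5.0, 40.0)
    head_intensity: tuple[float, float] = (0.7, 0.9)
    lesion_intensity: tuple[float, float] = (0.25, 0.4)
    background_texture_scale: tuple[float, float] = (8.0, 16.0)
    noise_sigma: tuple[float, float] = (0.02, 0.02)

    def validate(self, image_size: int) -> None:
        for name in (
            "head_radius",
            "lesion_fraction",
            "head_intensity",
            "lesion_intensity",
            "background_texture_scale",
            "noise_sigma",
        ):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise ValidationError(f"CohortRanges.{name}: invalid range ({lo}, {hi})")
        if self.center_jitter < 0:
            raise ValidationError("CohortRanges.center_jitter must be non-negative")
        if self.head_radius[1] + self.center_jitter > image_size / 2 - 1:
            raise ValidationError(
                "head_radius + center_jitter would push the head outside the image"
            )
        if not (0.0 <= self.lesion_fraction[0] and self.lesion_fraction[1] <= 100.0):
            raise ValidationError("lesion_fraction range must lie within [0, 100]")
        if self.lesion_intensity[1] >= self.head_intensity[0]:
            raise ValidationError(
                "lesion_intensity range must lie strictly below head_intensity range"
            )


def generate_cohort(
    n: int,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    image_size: int = 256,
) -> list[PhantomSample]:
    """Draw ``n`` phantom specs from ``ranges`` and render them.

    Per-sample seeds are derived from the master ``seed`` so the cohort is
    reproducible as a whole while individual samples remain independent.
    """
    if n < 1:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    ranges = ranges or CohortRanges()
    ranges.validate(image_size)
    rng = np.random.default_rng(seed)
    mid = (image_size - 1) / 2.0

    samples = []
    for _ in range(n):
        ry = rng.uniform(*ranges.head_radius)
        rx = rng.uniform(*ranges.head_radius)
        j = ranges.center_jitter
        cy = mid + rng.uniform(-j, j)
        cx = mid + rng.uniform(-j, j)
        spec = PhantomSpec(
            image_size=image_size,
            head_center=(float(cy), float(cx)),
            head_radii=(float(ry), float(rx)),
            lesion_fraction=float(rng.uniform(*ranges.lesion_fraction)),
            head_intensity=float(rng.uniform(*ranges.head_intensity)),
            lesion_intensity=float(rng.uniform(*ranges.lesion_intensity)),
            background_texture_scale=float(rng.uniform(*ranges.background_texture_scale)),
            noise_sigma=float(rng.uniform(*ranges.noise_sigma)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        samples.append(generate_phantom(spec))
    return samples


def healthy_spec(spec: PhantomSpec | None = None) -> PhantomSpec:
    """A lesion-free variant of ``spec`` (a head without osteonecrosis)."""
    return replace(spec or PhantomSpec(), lesion_fraction=0.0)
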