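"""Core value types passed between pipeline stages.

A *slice* is a single 2D grayscale axial MRI image with normalized
intensities; *region masks* (femoral head, necrotic region) are plain
boolean arrays aligned pixel-for-pixel with the slice they describe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from .errors import ValidationError

#: Binary per-pixel region label aligned to a Slice (femoral head or necrosis).
RegionMask = npt.NDArray[np.bool_]


@dataclass
class Slice:
    """One 2D grayscale image with pixel spacing and provenance metadata.

    ``pixels`` holds normalized intensities in [0, 1]; ``spacing`` is
    (mm/px, mm/px) for (row, col) and defaults to 1 mm isotropic, which is
    recorded but not used by any downstream computation.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    source_id: str = ""
    source_format: str = "array"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"Slice.pixels must be 2D (single slice, single channel), got ndim={self.pixels.ndim}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("Slice.pixels must be finite")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValidationError(
                f"Slice.pixels must be normalized to [0, 1], got range [{lo:g}, {hi:g}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def validate_mask(mask: np.ndarray, *, name: str = "mask") -> RegionMask:
    """Coerce to a boolean 2D array, rejecting anything else."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2D, got ndim={arr.ndim}")
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(f"{name} must be binary (0/1), found values {vals[:5]}")
        arr = arr.astype(bool)
    return arr


@dataclass
class DatasetSplit:
    """A reproducible train/test partition of slice identifiers."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    train_fraction: float

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValidationError(f"train/test overlap: {sorted(overlap)[:5]}")

    @property
    def n_total(self) -> int:
        return len(self.train_ids) + len(self.test_ids)


@dataclass
class ConfusionCounts:
    """Pixel-level confusion tallies from which all evaluation metrics derive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(f"ConfusionCounts.{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass
class TrainReport:
    """Per-epoch loss trajectory of one training run."""

    epochs_run: int
    final_train_loss: float
    history: dict[str, list[float]] = field(default_factory=dict)
    seed: int = 0
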