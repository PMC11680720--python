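"""Slice normalization, standard-size cropping, and the train/test split.

Every slice entering the segmentation network is min-max normalized to
[0, 1] and brought to a fixed 256x256 size: larger images are cropped
(centered by default, optionally on a user-supplied femoral-head center),
smaller ones are zero-padded symmetrically. The dataset split reserves a
random 80% of slices for training by default and is fully determined by
its seed.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np

from .datatypes import DatasetSplit, Slice
from .errors import DegenerateInputError, ValidationError

STANDARD_SIZE = 256


def normalize(
    raw: np.ndarray,
    spacing: tuple[float, float] = (1.0, 1.0),
    source_id: str = "",
    source_format: str = "array",
) -> Slice:
    """Min-max normalize a raw 2D intensity array to span exactly [0, 1]."""
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2D array, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("input intensities must be finite")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateInputError("constant image: no contrast to normalize")
    return Slice(
        pixels=(arr - lo) / (hi - lo),
        spacing=spacing,
        source_id=source_id,
        source_format=source_format,
    )


def _pad_axis(arr: np.ndarray, axis: int, size: int) -> np.ndarray:
    deficit = size - arr.shape[axis]
    if deficit <= 0:
        return arr
    before = deficit // 2  # extra pixel goes to bottom/right
    after = deficit - before
    widths = [(0, 0), (0, 0)]
    widths[axis] = (before, after)
    return np.pad(arr, widths)


def crop_to_standard(
    slc: Slice,
    center: tuple[float, float] | None = None,
    size: int = STANDARD_SIZE,
) -> Slice:
    """Crop (or zero-pad) a slice to ``size`` x ``size``.

    The crop window is centered on ``center`` (row, col) when given, else on
    the image center, and is clamped to stay inside the image. Axes shorter
    than ``size`` are zero-padded symmetrically, with the odd pixel going to
    the bottom/right. Idempotent on images already at the target size.
    """
    arr = slc.pixels
    pad_r = max(0, size - arr.shape[0])
    pad_c = max(0, size - arr.shape[1])
    if pad_r or pad_c:
        arr = _pad_axis(_pad_axis(arr, 0, size), 1, size)
        if center is not None:
            center = (center[0] + pad_r // 2, center[1] + pad_c // 2)
    if center is None:
        center = (arr.shape[0] / 2.0, arr.shape[1] / 2.0)

    starts = []
    for ax in range(2):
        start = int(round(center[ax] - size / 2.0))
        start = min(max(start, 0), arr.shape[ax] - size)
        starts.append(start)
    window = arr[starts[0] : starts[0] + size, starts[1] : starts[1] + size]
    return Slice(
        pixels=window,
        spacing=slc.spacing,
        source_id=slc.source_id,
        source_format=slc.source_format,
    )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_dataset(ids: Sequence[str], train_fraction: float = 0.8, seed: int = 0) -> DatasetSplit:
    """Randomly partition slice ids into train/test sets.

    The training set holds ``round(train_fraction * N)`` ids (half away from
    zero); the split is a pure function of ``ids`` order and ``seed``.
    """
    ids = list(ids)
    if not ids:
        raise ValidationError("ids must be non-empty")
    if len(set(ids)) != len(ids):
        raise ValidationError("ids must be unique")
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n_train = _round_half_away(train_fraction * len(ids))
    perm = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    return DatasetSplit(
        train_ids=shuffled[:n_train],
        test_ids=shuffled[n_train:],
        seed=seed,
        train_fraction=train_fraction,
    )


def write_split_manifest(split: DatasetSplit, path: str | Path) -> Path:
    """Write the split as a two-column CSV with the seed in a header comment."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# seed={split.seed} train_fraction={split.train_fraction}\n")
        writer = csv.writer(fh)
        writer.writerow(["source_id", "split"])
        for sid in split.train_ids:
            writer.writerow([sid, "train"])
        for sid in split.test_ids:
            writer.writerow([sid, "test"])
    return path


def read_split_manifest(path: str | Path) -> DatasetSplit:
    """Read back a manifest written by :func:`write_split_manifest`."""
    train, test, seed, frac = [], [], 0, 0.8
    with open(path) as fh:
        header = fh.readline().strip()
        if header.startswith("#"):
            for token in header[1:].split():
                key, _, val = token.partition("=")
                if key == "seed":
                    seed = int(val)
                elif key == "train_fraction":
                    frac = float(val)
        reader = csv.reader(fh)
        next(reader)  # column header
        for sid, part in reader:
            (train if part == "train" else test).append(sid)
    return DatasetSplit(train_ids=train, test_ids=test, seed=seed, train_fraction=frac)
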