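"""Readers and writers for the supported slice formats.

Supported inputs: 8/16-bit grayscale PNG, single-frame grayscale DICOM
(MONOCHROME2; MONOCHROME1 is inverted on load so brighter always means
higher signal), and single-slice NIfTI. Outputs: 8-bit PNG (intensity x 255,
rounded), 32-bit float NIfTI, and 0/1 binary masks in either format.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from PIL import Image

from .datatypes import RegionMask, Slice, validate_mask
from .errors import ValidationError

PNG_SUFFIXES = {".png"}
DICOM_SUFFIXES = {".dcm", ".dicom"}
NIFTI_SUFFIXES = {".nii"}  # plus .nii.gz, handled by name check


def _format_of(path: Path) -> str:
    name = path.name.lower()
    if path.suffix.lower() in PNG_SUFFIXES:
        return "png"
    if path.suffix.lower() in DICOM_SUFFIXES:
        return "dicom"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    raise ValidationError(f"unsupported image format: {path.name}")


def read_raw(path: str | Path) -> tuple[np.ndarray, tuple[float, float], str]:
    """Read a slice as raw (unnormalized) intensities.

    Returns ``(array, (row_mm, col_mm), format)``. The array is 2D float64;
    intensity scale is whatever the file stores.
    """
    path = Path(path)
    fmt = _format_of(path)
    spacing = (1.0, 1.0)
    if fmt == "png":
        with Image.open(path) as im:
            if im.mode not in ("L", "I", "I;16", "F"):
                im = im.convert("L")
            arr = np.asarray(im, dtype=np.float64)
    elif fmt == "dicom":
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        if arr.ndim != 2:
            raise ValidationError(f"multi-frame DICOM not supported: {path.name}")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
            arr = arr.max() - arr  # invert so bright = high signal
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None:
            spacing = (float(ps[0]), float(ps[1]))
    else:
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise ValidationError(f"NIfTI file is not a single slice: {path.name}")
        zooms = img.header.get_zooms()[:2]
        spacing = (float(zooms[0]), float(zooms[1]))
    if arr.ndim != 2:
        raise ValidationError(f"expected a single 2D slice in {path.name}")
    return arr, spacing, fmt


def write_slice(slc: Slice, path: str | Path) -> Path:
    """Write a normalized slice as 8-bit PNG or 32-bit float NIfTI."""
    path = Path(path)
    fmt = _format_of(path)
    if fmt == "png":
        data = np.rint(slc.pixels * 255.0).astype(np.uint8)
        Image.fromarray(data, mode="L").save(path)
    elif fmt == "nifti":
        affine = np.diag([slc.spacing[0], slc.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(slc.pixels.astype(np.float32), affine), str(path))
    else:
        raise ValidationError(f"cannot write format {fmt}; use PNG or NIfTI")
    return path


def write_mask(mask: RegionMask, path: str | Path) -> Path:
    """Write a binary mask with values 0/1 (PNG or NIfTI)."""
    mask = validate_mask(mask)
    path = Path(path)
    fmt = _format_of(path)
    if fmt == "png":
        Image.fromarray(mask.astype(np.uint8), mode="L").save(path)
    elif fmt == "nifti":
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), str(path))
    else:
        raise ValidationError(f"cannot write format {fmt}; use PNG or NIfTI")
    return path


def read_mask(path: str | Path) -> RegionMask:
    """Read a binary mask; any nonzero pixel counts as foreground."""
    arr, _, _ = read_raw(path)
    return arr > 0
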