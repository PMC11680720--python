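"""Severity grading and report rendering.

The necrotic proportion (percent of femoral-head area involved, at pixel
level) maps to the early-stage severity grades used clinically with the
Steinberg system: Mild below 15%, Moderate from 15% to 30% inclusive,
Severe above 30%. Proportions below 0.1% are reported as "Without ONFH".
Grading uses full floating precision; rounding applies only to display.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.segmentation import find_boundaries

from .datatypes import RegionMask, Slice, validate_mask
from .errors import DegenerateInputError, NoFemoralHeadError, ValidationError
from .necrosis import adaptive_threshold, compute_proportion

__all__ = ["Grade", "GradeReport", "assign_grade", "render_report", "grade_slice"]

logger = logging.getLogger(__name__)

WITHOUT_ONFH_CUTOFF = 0.1  # percent
MILD_MODERATE_BOUNDARY = 15.0
MODERATE_SEVERE_BOUNDARY = 30.0


class Grade(Enum):
    """Early-stage severity grade by necrotic area share."""

    WITHOUT_ONFH = "Without ONFH"
    MILD = "Mild"
    MODERATE = "Moderate"
    SEVERE = "Severe"

    @property
    def severity(self) -> int:
        return list(Grade).index(self)


def assign_grade(proportion: float) -> Grade:
    """Map a necrotic proportion (percent) to its severity grade.

    Boundaries: < 0.1 -> Without ONFH; [0.1, 15) -> Mild; [15, 30] ->
    Moderate; (30, 100] -> Severe.
    """
    if not np.isfinite(proportion) or not (0.0 <= proportion <= 100.0):
        raise ValidationError(f"proportion must be in [0, 100], got {proportion}")
    if proportion < WITHOUT_ONFH_CUTOFF:
        return Grade.WITHOUT_ONFH
    if proportion < MILD_MODERATE_BOUNDARY:
        return Grade.MILD
    if proportion <= MODERATE_SEVERE_BOUNDARY:
        return Grade.MODERATE
    return Grade.SEVERE


@dataclass
class GradeReport:
    """Per-slice diagnostic result."""

    proportion: float  # percent, full precision
    grade: Grade
    threshold_used: float  # intensity cutoff; NaN when no threshold was computed
    source_id: str = ""
    overlay_path: str = ""
    note: str = ""

    def to_json_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "proportion": round(self.proportion, 2),
            "grade": self.grade.value,
            "threshold": None if np.isnan(self.threshold_used) else round(self.threshold_used, 6),
            "overlay": self.overlay_path,
            "note": self.note,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GradeReport":
        return cls(
            proportion=float(d["proportion"]),
            grade=Grade(d["grade"]),
            threshold_used=float("nan") if d["threshold"] is None else float(d["threshold"]),
            source_id=d.get("source_id", ""),
            overlay_path=d.get("overlay", ""),
            note=d.get("note", ""),
        )


# Overlay palette (R, G, B): head outline green, necrotic pixels tinted red.
_OUTLINE = np.array([0, 255, 0], dtype=np.float64)
_NECROSIS_TINT = np.array([255, 40, 40], dtype=np.float64)


def make_overlay(slc: Slice, head_mask: RegionMask, necrosis_mask: RegionMask) -> np.ndarray:
    """RGB uint8 overlay: grayscale base, head outlined, necrosis tinted."""
    head_mask = validate_mask(head_mask, name="head_mask")
    necrosis_mask = validate_mask(necrosis_mask, name="necrosis_mask")
    if head_mask.shape != slc.pixels.shape or necrosis_mask.shape != slc.pixels.shape:
        raise ValidationError("masks must be aligned to the slice")
    base = np.rint(slc.pixels * 255.0)
    rgb = np.repeat(base[:, :, None], 3, axis=2)
    if necrosis_mask.any():
        rgb[necrosis_mask] = 0.5 * rgb[necrosis_mask] + 0.5 * _NECROSIS_TINT
    if head_mask.any():
        outline = find_boundaries(head_mask, mode="outer")
        rgb[outline] = _OUTLINE
    return np.rint(rgb).astype(np.uint8)


def render_report(
    slc: Slice,
    head_mask: RegionMask,
    necrosis_mask: RegionMask,
    report: GradeReport,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the overlay PNG and the JSON record; returns their paths.

    Output bytes are deterministic for fixed inputs: the overlay depends only
    on the pixel data and masks, and the JSON is written with sorted keys and
    no timestamps.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = report.source_id or "slice"
    overlay_path = out_dir / f"{stem}_overlay.png"
    json_path = out_dir / f"{stem}_report.json"

    Image.fromarray(make_overlay(slc, head_mask, necrosis_mask), mode="RGB").save(overlay_path)
    report.overlay_path = overlay_path.name
    with open(json_path, "w") as fh:
        json.dump(report.to_json_dict(), fh, sort_keys=True, indent=2)
        fh.write("\n")
    return overlay_path, json_path


def grade_slice(
    slc: Slice,
    head_mask: RegionMask,
    polarity: str = "dark",
) -> tuple[GradeReport, RegionMask]:
    """Quantify and grade one slice given its femoral-head mask.

    Degenerate cases follow the diagnostic contract: an empty head mask or a
    contrast-free head region cannot harbor a detectable lesion, so both map
    to proportion 0 ("Without ONFH") with an explanatory note and a warning.
    """
    empty = np.zeros(slc.pixels.shape, dtype=bool)
    try:
        result = adaptive_threshold(slc, head_mask, polarity=polarity)
    except NoFemoralHeadError:
        warnings.warn("no femoral head found; reporting Without ONFH", stacklevel=2)
        report = GradeReport(0.0, Grade.WITHOUT_ONFH, float("nan"), slc.source_id,
                             note="no femoral head found")
        return report, empty
    except DegenerateInputError:
        warnings.warn("contrast-free head region; reporting Without ONFH", stacklevel=2)
        report = GradeReport(0.0, Grade.WITHOUT_ONFH, float("nan"), slc.source_id,
                             note="head region has no intensity contrast")
        return report, empty

    proportion = compute_proportion(result.necrosis_mask, head_mask)
    report = GradeReport(
        proportion=proportion,
        grade=assign_grade(proportion),
        threshold_used=result.threshold,
        source_id=slc.source_id,
    )
    return report, result.necrosis_mask
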