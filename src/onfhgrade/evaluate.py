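"""Pixel-level evaluation of segmentation and end-to-end grading.

The four standard metrics — accuracy, sensitivity, specificity and positive
predictive value — derive from a pixel confusion table; Dice is reported
alongside as the usual segmentation overlap score. Metrics can be pooled
over all test pixels (one confusion table, the default) or macro-averaged
per image. The end-to-end harness additionally reports grade agreement: the
share of samples whose assigned grade matches the grade implied by the
ground-truth necrotic proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import ConfusionCounts, RegionMask, validate_mask
from .errors import ValidationError
from .grading import Grade, assign_grade, grade_slice
from .phantom import PhantomSample
from .segnet import DualSupervisedUNet, segment

__all__ = ["ConfusionCounts", "MetricReport", "PipelineReport", "confusion", "metrics",
           "dice_coefficient", "evaluate_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    """Percent-scale segmentation metrics; undefined ratios are NaN, never 0."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    dice: float  # auxiliary overlap score, proportion in [0, 1]
    n_images: int = 1
    pooled: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "dice": self.dice,
        }


def confusion(pred: RegionMask, truth: RegionMask) -> ConfusionCounts:
    """Pixel confusion counts between a predicted and a true mask."""
    pred = validate_mask(pred, name="pred")
    truth = validate_mask(truth, name="truth")
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined: zero denominator", name)
        return float("nan")
    return 100.0 * num / den


def metrics(counts: ConfusionCounts, n_images: int = 1, pooled: bool = True) -> MetricReport:
    """Accuracy, sensitivity, specificity and PPV (percent) plus Dice."""
    if counts.total == 0:
        raise ValidationError("all confusion counts are zero")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    dice_den = 2 * tp + fp + fn
    return MetricReport(
        accuracy=_ratio(tp + tn, counts.total, "accuracy"),
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
        specificity=_ratio(tn, tn + fp, "specificity"),
        ppv=_ratio(tp, tp + fp, "PPV"),
        dice=(2 * tp / dice_den) if dice_den else float("nan"),
        n_images=n_images,
        pooled=pooled,
    )


def dice_coefficient(pred: RegionMask, truth: RegionMask) -> float:
    """2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    c = confusion(pred, truth)
    den = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / den if den else 1.0


def _macro_average(reports: list[MetricReport]) -> MetricReport:
    def mean_of(attr: str) -> float:
        vals = np.array([getattr(r, attr) for r in reports])
        return float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")

    return MetricReport(
        accuracy=mean_of("accuracy"),
        sensitivity=mean_of("sensitivity"),
        specificity=mean_of("specificity"),
        ppv=mean_of("ppv"),
        dice=mean_of("dice"),
        n_images=len(reports),
        pooled=False,
    )


@dataclass
class PipelineReport:
    """End-to-end evaluation over a set of samples with known ground truth."""

    segmentation: MetricReport
    grade_agreement: float  # fraction of samples graded identically to truth
    per_grade: dict[str, dict[str, int]] = field(default_factory=dict)
    mean_head_dice: float = float("nan")
    mean_proportion_error: float = float("nan")  # mean |predicted - true|, pp


def evaluate_pipeline(
    model: DualSupervisedUNet,
    samples: list[PhantomSample],
    pooled: bool = True,
    segmenter=None,
) -> PipelineReport:
    """Run segment -> threshold -> grade on every sample and score it.

    ``segmenter`` may replace the model-based segmentation with any callable
    ``sample -> head_mask`` (e.g. a ground-truth oracle for upper-bound
    checks).
    """
    if not samples:
        raise ValidationError("evaluation requires at least one sample")

    total = ConfusionCounts(0, 0, 0, 0)
    per_image: list[MetricReport] = []
    dices: list[float] = []
    prop_errors: list[float] = []
    agree = 0
    per_grade: dict[str, dict[str, int]] = {}

    for sample in samples:
        if segmenter is not None:
            head_pred = validate_mask(segmenter(sample), name="segmenter output")
        else:
            head_pred = segment(model, sample.image).head_mask
        c = confusion(head_pred, sample.head_mask)
        total = total + c
        per_image.append(metrics(c, n_images=1, pooled=False))
        dices.append(dice_coefficient(head_pred, sample.head_mask))

        report, _ = grade_slice(sample.image, head_pred)
        true_grade = assign_grade(sample.true_proportion)
        if report.grade is not Grade.WITHOUT_ONFH or report.note == "":
            prop_errors.append(abs(report.proportion - sample.true_proportion))
        if report.grade is true_grade:
            agree += 1
        row = per_grade.setdefault(true_grade.value, {})
        row[report.grade.value] = row.get(report.grade.value, 0) + 1

    seg_report = (
        metrics(total, n_images=len(samples), pooled=True)
        if pooled
        else _macro_average(per_image)
    )
    return PipelineReport(
        segmentation=seg_report,
        grade_agreement=agree / len(samples),
        per_grade=per_grade,
        mean_head_dice=float(np.mean(dices)),
        mean_proportion_error=float(np.mean(prop_errors)) if prop_errors else float("nan"),
    )
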