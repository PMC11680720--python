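"""Score segmentation and grading against ground truth.

Shows the pixel confusion table, the four derived metrics (accuracy,
sensitivity, specificity, PPV) with Dice, and the end-to-end grade
agreement, using the ground-truth oracle segmenter so the numbers isolate
the thresholding and grading stages.
"""

from onfhgrade import confusion, generate_cohort, metrics
from onfhgrade.evaluate import evaluate_pipeline

samples = generate_cohort(8, seed=9)

# Pixel metrics of a deliberately imperfect prediction: erode the truth.
from scipy.ndimage import binary_erosion

s = samples[0]
pred = binary_erosion(s.head_mask, iterations=2)
c = confusion(pred, s.head_mask)
print(f"confusion counts: tp={c.tp} fp={c.fp} tn={c.tn} fn={c.fn}")
m = metrics(c)
print(
    f"accuracy {m.accuracy:.2f}%  sensitivity {m.sensitivity:.2f}%  "
    f"specificity {m.specificity:.2f}%  PPV {m.ppv:.2f}%  Dice {m.dice:.4f}"
)

# End-to-end with the oracle segmenter: upper bound of the grading stage.
report = evaluate_pipeline(None, samples, segmenter=lambda s: s.head_mask)
print(f"grade agreement with ground truth: {report.grade_agreement:.2f}")
print(f"mean |proportion error|: {report.mean_proportion_error:.3f} percentage points")
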