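"""Tapping-panel-dryness (TPD) severity grading.

Severity is graded 1 (mild) to 5 (severe) from the area ratio
lambda = S1/S2 of latex pixels to tapping-cut pixels.  The bands are
inclusive on their upper ends: grade 5 for lambda <= 10% (including
ratios below 1%, which occur in severe panels), 4 for 10% < lambda <= 20%,
3 for 20% < lambda <= 35%, 2 for 35% < lambda <= 45%, and 1 above 45%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GradeResult", "compute_lambda", "assign_grade", "grade_from_counts",
           "grade_segmentation"]


class NoScarError(ValueError):
    """The scar mask is empty; the area ratio (and grade) is undefined."""


@dataclass(frozen=True)
class GradeResult:
    latex_area: int  # S1
    scar_area: int  # S2
    ratio: float  # lambda = S1/S2
    grade: int


def compute_lambda(latex_mask, scar_mask):
    """Pixel areas S1 (latex), S2 (scar) and their ratio lambda = S1/S2."""
    latex = np.asarray(latex_mask, dtype=bool)
    scar = np.asarray(scar_mask, dtype=bool)
    if latex.shape != scar.shape:
        raise ValueError("masks must have the same shape")
    s1 = int(latex.sum())
    s2 = int(scar.sum())
    if s2 == 0:
        raise NoScarError("scar mask is empty; grading impossible")
    return s1, s2, s1 / s2


def assign_grade(ratio: float) -> int:
    """Severity grade from the latex-to-cut area ratio (monotone non-increasing)."""
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if ratio > 0.45:
        return 1
    if ratio > 0.35:
        return 2
    if ratio > 0.20:
        return 3
    if ratio > 0.10:
        return 4
    return 5


def grade_from_counts(latex_area: int, scar_area: int) -> GradeResult:
    """Grade directly from pixel counts (e.g. a batch table row)."""
    if scar_area <= 0:
        raise NoScarError("scar area must be positive")
    ratio = latex_area / scar_area
    return GradeResult(
        latex_area=int(latex_area),
        scar_area=int(scar_area),
        ratio=ratio,
        grade=assign_grade(ratio),
    )


def grade_segmentation(result) -> GradeResult:
    """Grade a :class:`~dbotsu.pipeline.SegmentationResult`."""
    s1, s2, ratio = compute_lambda(result.latex_mask, result.scar_mask)
    return GradeResult(latex_area=s1, scar_area=s2, ratio=ratio, grade=assign_grade(ratio))
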