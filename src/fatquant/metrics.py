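"""Segmentation-agreement metrics and the occupation ratio.

Conventions: the Dice similarity coefficient is a fraction in [0, 1] (with
DSC > 0.70 conventionally read as excellent agreement); accuracy,
sensitivity and specificity are percentages computed pixel-wise over the
full image frame; the relative area difference (RAD) is a signed percentage,
positive when the prediction underestimates the ground-truth area.  The
signed form is the default: a cohort whose RAD standard deviation dwarfs its
mean is only possible when under- and over-estimation carry opposite signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .imaging_io import RegionMasks

#: Dice level conventionally reported as excellent agreement.
DSC_EXCELLENT = 0.70


@dataclass
class SegMetricReport:
    """Agreement metrics for one region pair; NaN marks undefined ratios."""

    region: str
    dsc: float
    accuracy: float
    sensitivity: float
    specificity: float
    rad_pct: float

    @property
    def excellent(self) -> bool:
        return self.dsc > DSC_EXCELLENT

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "dsc": self.dsc,
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "rad_pct": self.rad_pct,
            "excellent_agreement": bool(self.excellent),
        }


def _pair(gt, pred):
    gt = np.asarray(gt, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if gt.shape != pred.shape:
        raise DataError(f"mask shapes differ: {gt.shape} vs {pred.shape}")
    return gt, pred


def dice(ground_truth: np.ndarray, prediction: np.ndarray) -> float:
    """Dice similarity: 2|A∩B| / (|A|+|B|); two empty masks agree vacuously (1)."""
    gt, pred = _pair(ground_truth, prediction)
    a, b = int(gt.sum()), int(pred.sum())
    if a + b == 0:
        return 1.0
    return 2.0 * int((gt & pred).sum()) / (a + b)


def pixel_classification_metrics(ground_truth: np.ndarray, prediction: np.ndarray):
    """(accuracy, sensitivity, specificity) in percent over the full frame.

    An empty denominator (no positives, or no negatives) yields NaN for the
    affected rate rather than a silent zero.
    """
    gt, pred = _pair(ground_truth, prediction)
    tp = int((gt & pred).sum())
    tn = int((~gt & ~pred).sum())
    fp = int((~gt & pred).sum())
    fn = int((gt & ~pred).sum())
    total = gt.size
    accuracy = 100.0 * (tp + tn) / total
    sensitivity = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    specificity = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return accuracy, sensitivity, specificity


def relative_area_difference(ground_truth: np.ndarray, prediction: np.ndarray,
                             signed: bool = True) -> float:
    """RAD in percent: (|A_gt| - |A_pred|) / |A_gt| * 100.

    Positive means the prediction underestimates.  ``signed=False`` returns
    the magnitude.
    """
    gt, pred = _pair(ground_truth, prediction)
    a = int(gt.sum())
    if a == 0:
        raise DataError("RAD undefined for empty ground truth")
    rad = 100.0 * (a - int(pred.sum())) / a
    return rad if signed else abs(rad)


def occupation_ratio(masks: RegionMasks) -> float:
    """Muscle area over fossa area; the atrophy index of the Y-view slice."""
    if masks.fossa_area == 0:
        raise DataError("occupation ratio undefined for empty fossa")
    return masks.muscle_area / masks.fossa_area


def region_report(ground_truth: np.ndarray, prediction: np.ndarray,
                  region: str = "") -> SegMetricReport:
    """All agreement metrics for one ground-truth/prediction mask pair."""
    acc, sens, spec = pixel_classification_metrics(ground_truth, prediction)
    return SegMetricReport(
        region=region,
        dsc=dice(ground_truth, prediction),
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        rad_pct=relative_area_difference(ground_truth, prediction),
    )


def masks_report(ground_truth: RegionMasks, prediction: RegionMasks) -> list[SegMetricReport]:
    """Fossa and muscle reports for a pair of two-region annotations."""
    return [
        region_report(ground_truth.fossa, prediction.fossa, region="fossa"),
        region_report(ground_truth.muscle, prediction.muscle, region="muscle"),
    ]
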