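"""Region-restricted adaptive Otsu quantification of fatty infiltration.

The quantifier works entirely inside the annotated muscle ROI of an 8-bit
slice:

1. the population standard deviation of the ROI intensities is computed;
2. when it reaches the gate (default 35 gray levels) the ROI histogram is
   equalised in place — severely degenerated muscle expresses fat at several
   intensity stages with unclear boundaries, and equalisation stabilises the
   threshold there, while for mildly affected muscle it would wash the
   threshold out, hence the gate;
3. Otsu's threshold is selected on the 256-bin ROI histogram by exhaustively
   maximising the between-class variance (class 0 = levels <= t, class 1 =
   levels > t; a threshold that empties a class scores zero; ties resolve to
   the lowest t);
4. pixels strictly above the threshold are classified fat, and the fatty
   infiltration is the fat share of the ROI in percent.

Two guarded degeneracies make fat-free muscle read as 0% rather than ~50%:
a single-intensity ROI returns that intensity as the threshold (no pixel lies
above it), and an ROI whose best Otsu split has low separability
(eta = between-class / total variance below ``min_separability``) is declared
fat-free — a unimodal noise-only ROI has eta around 2/pi ~ 0.64 whereas even
a few percent of bright fat at a clinically plausible intensity gap pushes
eta above 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .imaging_io import GrayscaleSlice

#: Gate on the ROI intensity standard deviation above which the ROI is
#: equalised before thresholding.  Calibrated on clinically graded data:
#: grade-2 ROIs averaged SD 28.47 (upper limit ~35.95) and grade-3 ROIs
#: averaged 35.18, so 35 separates moderate from severe infiltration.
#: Documented constants, not recomputed here.
SD_GATE_DEFAULT = 35.0
GRADE2_SD_MEAN = 28.47
GRADE2_SD_UPPER = 35.95
GRADE3_SD_MEAN = 35.18

#: Default separability floor for the no-fat guard (see module docstring).
MIN_SEPARABILITY_DEFAULT = 0.70

#: Smallest usable muscle ROI, in pixels; below this an annotation is unusable.
MIN_ROI_AREA = 16


@dataclass
class OtsuResult:
    """Outcome of fat quantification for one muscle ROI."""

    threshold: int
    equalization_applied: bool
    roi_sd: float
    fat_mask: np.ndarray
    fatty_infiltration_pct: float
    separability: float
    separable: bool

    def to_dict(self) -> dict:
        return {
            "threshold_gray_level": int(self.threshold),
            "equalization_applied": bool(self.equalization_applied),
            "roi_sd_gray_levels": float(self.roi_sd),
            "fatty_infiltration_pct": float(self.fatty_infiltration_pct),
            "separability": float(self.separability),
            "separable": bool(self.separable),
            "fat_pixels": int(self.fat_mask.sum()),
        }


def _as_pixels(slc: GrayscaleSlice | np.ndarray) -> np.ndarray:
    arr = slc.pixels if isinstance(slc, GrayscaleSlice) else np.asarray(slc)
    if arr.dtype != np.uint8:
        raise DataError("quantification operates on the 8-bit analysis scale")
    return arr


def roi_histogram(slc: GrayscaleSlice | np.ndarray, muscle: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of the muscle ROI (bin b = count at level b)."""
    arr = _as_pixels(slc)
    muscle = np.asarray(muscle, dtype=bool)
    if muscle.shape != arr.shape:
        raise DataError(f"mask shape {muscle.shape} != slice shape {arr.shape}")
    if not muscle.any():
        raise DataError("empty muscle mask")
    return np.bincount(arr[muscle], minlength=256).astype(np.int64)


def otsu_threshold(hist: np.ndarray, return_variance: bool = False):
    """Otsu's threshold on a 256-bin histogram by exhaustive search.

    Scans every candidate t in 0..255 with class 0 = levels <= t and class 1 =
    levels > t, scoring the between-class variance w0*w1*(mu0-mu1)^2 (zero if
    a class is empty) and returning the lowest maximising t.  A histogram with
    a single occupied level returns that level, so no pixel classifies as fat.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.ndim != 1 or hist.size != 256:
        raise DataError(f"expected a 256-bin histogram, got shape {hist.shape}")
    total = hist.sum()
    if total <= 0:
        raise DataError("all-zero histogram")
    levels = np.arange(256, dtype=np.float64)
    p = hist / total
    w0 = np.cumsum(p)
    m = np.cumsum(p * levels)
    mu_total = m[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m / w0
        mu1 = (mu_total - m) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 <= 0) | (w1 <= 0), 0.0, sigma_b)
    occupied = np.flatnonzero(hist)
    if occupied.size == 1:  # degenerate single-level ROI: threshold at that level
        t = int(occupied[0])
        return (t, 0.0) if return_variance else t
    t = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximiser
    return (t, float(sigma_b[t])) if return_variance else t


def equalize_roi(slc: GrayscaleSlice | np.ndarray, muscle: np.ndarray) -> GrayscaleSlice:
    """Histogram-equalise the muscle ROI in place; outside pixels untouched.

    The CDF is computed from ROI pixels only and each ROI pixel maps to
    ``round(255 * cdf(v))`` — monotone, range-preserving, and a single-valued
    ROI passes through unchanged.
    """
    arr = _as_pixels(slc)
    hist = roi_histogram(arr, muscle)  # validates the mask
    if np.count_nonzero(hist) < 2:
        out = arr.copy()
    else:
        cdf = np.cumsum(hist) / hist.sum()
        lut = np.floor(255.0 * cdf + 0.5).astype(np.uint8)
        out = arr.copy()
        muscle = np.asarray(muscle, dtype=bool)
        out[muscle] = lut[arr[muscle]]
    if isinstance(slc, GrayscaleSlice):
        return GrayscaleSlice(out, source_id=slc.source_id, laterality=slc.laterality,
                              metadata={**slc.metadata, "roi_equalized": True})
    return GrayscaleSlice(out, metadata={"roi_equalized": True})


def quantify_fat(
    slc: GrayscaleSlice | np.ndarray,
    muscle: np.ndarray,
    sd_gate: float | None = SD_GATE_DEFAULT,
    min_separability: float = MIN_SEPARABILITY_DEFAULT,
    min_roi_area: int = MIN_ROI_AREA,
) -> OtsuResult:
    """Quantify fatty infiltration inside *muscle* (see module docstring).

    ``sd_gate=None`` disables equalisation entirely; ``min_separability=0``
    disables the no-fat guard.  Only pixels inside the mask ever influence
    the result.
    """
    arr = _as_pixels(slc)
    muscle = np.asarray(muscle, dtype=bool)
    if muscle.shape != arr.shape:
        raise DataError(f"mask shape {muscle.shape} != slice shape {arr.shape}")
    area = int(muscle.sum())
    if area < min_roi_area:
        raise DataError(f"muscle ROI has {area} px, below the usable floor of {min_roi_area}")

    roi = arr[muscle]
    roi_sd = float(roi.std())  # population SD on the 8-bit scale
    equalized = sd_gate is not None and roi_sd >= sd_gate
    work = equalize_roi(arr, muscle).pixels if equalized else arr

    hist = roi_histogram(work, muscle)
    t, sigma_b = otsu_threshold(hist, return_variance=True)
    work_roi = work[muscle]
    total_var = float(work_roi.astype(np.float64).var())
    separability = sigma_b / total_var if total_var > 0 else 0.0

    separable = total_var > 0 and separability >= min_separability
    if not separable:
        t = int(work_roi.max())  # declare fat-free: nothing lies above the max
    fat_mask = np.zeros_like(muscle)
    fat_mask[muscle] = work_roi > t
    fi = 100.0 * float(fat_mask.sum()) / area
    return OtsuResult(threshold=int(t), equalization_applied=bool(equalized),
                      roi_sd=roi_sd, fat_mask=fat_mask, fatty_infiltration_pct=fi,
                      separability=float(separability), separable=bool(separable))


def render_fat_image(result: OtsuResult, muscle: np.ndarray) -> np.ndarray:
    """Binary rendering of the ROI: white (255) = fat, black (0) = muscle.

    Pixels outside the ROI are also 0, matching the post-processed final
    binary image convention.
    """
    muscle = np.asarray(muscle, dtype=bool)
    out = np.zeros(muscle.shape, dtype=np.uint8)
    out[result.fat_mask] = 255
    return out
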