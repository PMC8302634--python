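"""Reading, writing and normalising slices, label maps and grade sidecars.

Everything downstream (histograms, the SD gate, Otsu) is stated on a fixed
8-bit gray scale, so every slice entering analysis is normalised to integer
intensities in [0, 255] here, once.  The default policy is per-slice min-max;
a percentile-clipping variant is available for data with hot outliers.
8-bit sources are passed through unchanged so that PNG fixtures survive a
round trip bit-exactly.

Label maps follow the ITK-SNAP idiom of one integer label per pixel.  Because
the muscle is annotated *inside* the fossa, a single-label-per-pixel map
cannot carry both memberships for a muscle pixel; the convention here is that
the muscle label implies fossa membership, and a dedicated third label
(``violation_label``) marks predicted muscle pixels lying outside the
predicted fossa so that prediction round trips stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DataError, ImageIOError, UsageError

Laterality = Literal["left", "right", "unknown"]

#: Default ITK-SNAP-style label values.
FOSSA_LABEL = 1
MUSCLE_LABEL = 2
#: Label for predicted muscle pixels outside the predicted fossa.
VIOLATION_LABEL = 3


@dataclass
class GrayscaleSlice:
    """One 2-D intensity image on the common 8-bit analysis scale."""

    pixels: np.ndarray  # uint8, shape (H, W)
    source_id: str = ""
    laterality: Laterality = "unknown"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise DataError(f"slice must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 32 or self.pixels.shape[1] < 32:
            raise DataError(f"slice too small for analysis: {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise DataError("slice intensities outside [0, 255]; normalise first")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class RegionMasks:
    """Paired fossa and muscle binary masks aligned to one slice.

    For ground truth the muscle must lie inside the fossa; predictions may
    violate containment and the violation pixel count is always reportable.
    """

    fossa: np.ndarray
    muscle: np.ndarray

    def __post_init__(self) -> None:
        self.fossa = np.asarray(self.fossa).astype(bool)
        self.muscle = np.asarray(self.muscle).astype(bool)
        if self.fossa.shape != self.muscle.shape:
            raise DataError(
                f"fossa {self.fossa.shape} and muscle {self.muscle.shape} shapes differ"
            )

    @property
    def fossa_area(self) -> int:
        return int(self.fossa.sum())

    @property
    def muscle_area(self) -> int:
        return int(self.muscle.sum())

    @property
    def containment_violations(self) -> int:
        """Number of muscle pixels outside the fossa."""
        return int((self.muscle & ~self.fossa).sum())

    def require_valid(self, ground_truth: bool = False, tolerance: int = 0) -> "RegionMasks":
        """Validate areas (and containment when *ground_truth*)."""
        if self.fossa_area == 0:
            raise DataError("fossa mask is empty")
        if self.muscle_area == 0:
            raise DataError("muscle mask is empty")
        if ground_truth and self.containment_violations > tolerance:
            raise DataError(
                f"{self.containment_violations} muscle pixels outside fossa "
                f"(tolerance {tolerance}) in ground-truth masks"
            )
        return self


@dataclass(frozen=True)
class GradeLabel:
    """Goutallier grade: 0 normal ... 4 more fat than muscle."""

    grade: int

    def __post_init__(self) -> None:
        if self.grade not in (0, 1, 2, 3, 4):
            raise DataError(f"Goutallier grade must be in 0..4, got {self.grade}")


def normalize_to_8bit(
    raw: np.ndarray,
    policy: str = "minmax",
    p_lo: float | None = None,
    p_hi: float | None = None,
    source_id: str = "",
    laterality: Laterality = "unknown",
) -> GrayscaleSlice:
    """Map arbitrary-depth intensities onto the integer 0-255 analysis scale.

    ``minmax`` maps the observed range onto [0, 255] with round-half-up;
    ``percentile`` first clips to the [p_lo, p_hi] percentile band.  The map
    is monotone, a constant image maps to all zeros, and already-8-bit input
    spanning the full range is a fixed point.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2:
        raise DataError(f"expected a 2-D array, got shape {raw.shape}")
    if policy == "percentile":
        if p_lo is None or p_hi is None or not (0 <= p_lo < p_hi <= 100):
            raise UsageError(f"percentile policy needs 0 <= p_lo < p_hi <= 100, got {p_lo}, {p_hi}")
        lo, hi = np.percentile(raw, [p_lo, p_hi])
        raw = np.clip(raw, lo, hi)
    elif policy != "minmax":
        raise UsageError(f"unknown normalization policy {policy!r}")
    vmin, vmax = raw.min(), raw.max()
    if vmax == vmin:  # documented degenerate convention
        out = np.zeros(raw.shape, dtype=np.uint8)
    else:
        scaled = (raw - vmin) * 255.0 / (vmax - vmin)
        out = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
    meta = {"normalization": policy, "input_min": float(vmin), "input_max": float(vmax)}
    return GrayscaleSlice(out, source_id=source_id, laterality=laterality, metadata=meta)


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".png"):
        return "png"
    if name.endswith((".dcm", ".dicom", ".ima")):
        return "dicom"
    raise UsageError(f"cannot infer image format from {path.name!r}; pass format explicitly")


def read_slice(
    path: str | Path,
    format: str | None = None,
    slice_index: int | None = None,
    policy: str = "minmax",
    p_lo: float | None = None,
    p_hi: float | None = None,
) -> GrayscaleSlice:
    """Read one slice from PNG, single-frame DICOM, or a NIfTI (volume needs *slice_index*).

    8-bit sources pass through unchanged; deeper sources are normalised under
    *policy*.  The original bit depth and source range go into metadata.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    fmt = format or _infer_format(path)

    if fmt == "png":
        import imageio.v3 as iio

        try:
            arr = iio.imread(path)
        except Exception as exc:
            raise ImageIOError(f"could not read PNG {path}: {exc}") from exc
        if arr.ndim == 3:  # accept flat RGB(A) exports of grayscale data
            if not (arr[..., 0] == arr[..., 1]).all():
                raise DataError(f"{path} is a colour image, not grayscale")
            arr = arr[..., 0]
    elif fmt == "dicom":
        import pydicom

        try:
            ds = pydicom.dcmread(path)
            n_frames = int(getattr(ds, "NumberOfFrames", 1))
            arr = ds.pixel_array
        except ImageIOError:
            raise
        except Exception as exc:
            raise ImageIOError(f"could not read DICOM {path}: {exc}") from exc
        if n_frames > 1 or arr.ndim == 3:
            if slice_index is None:
                raise UsageError(f"{path} is multi-frame; a slice_index is required")
            arr = arr[slice_index]
    elif fmt == "nifti":
        import nibabel as nib

        try:
            img = nib.load(path)
            arr = np.asanyarray(img.dataobj)
        except Exception as exc:
            raise ImageIOError(f"could not read NIfTI {path}: {exc}") from exc
        arr = np.squeeze(arr)
        if arr.ndim == 3:
            if slice_index is None:
                raise UsageError(f"{path} is a volume; a slice_index is required")
            arr = arr[:, :, slice_index]
        elif arr.ndim != 2:
            raise DataError(f"{path}: unsupported dimensionality {arr.ndim}")
    else:
        raise UsageError(f"unknown format {fmt!r}")

    source_id = path.name
    orig_dtype = str(arr.dtype)
    if arr.dtype == np.uint8:
        out = GrayscaleSlice(arr, source_id=source_id)
        out.metadata["normalization"] = "identity"
    else:
        out = normalize_to_8bit(arr, policy=policy, p_lo=p_lo, p_hi=p_hi, source_id=source_id)
    out.metadata["source_dtype"] = orig_dtype
    out.metadata["path"] = str(path)
    return out


def write_slice(path: str | Path, slc: GrayscaleSlice | np.ndarray) -> None:
    """Write an 8-bit slice or binary mask as grayscale PNG (masks as 0/255)."""
    import imageio.v3 as iio

    arr = slc.pixels if isinstance(slc, GrayscaleSlice) else np.asarray(slc)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    iio.imwrite(Path(path), arr.astype(np.uint8))


def read_label_map(
    path: str | Path,
    fossa_label: int = FOSSA_LABEL,
    muscle_label: int = MUSCLE_LABEL,
    slice_index: int | None = None,
    violation_label: int | None = VIOLATION_LABEL,
    muscle_implies_fossa: bool = True,
    ground_truth: bool = False,
) -> RegionMasks:
    """Extract fossa and muscle masks from an integer label map (NIfTI or PNG).

    Under the default convention muscle pixels count as fossa too (the muscle
    is painted inside the fossa, one label per pixel), and *violation_label*
    marks muscle-outside-fossa pixels as written by :func:`write_label_map`.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    fmt = _infer_format(path)
    if fmt == "nifti":
        import nibabel as nib

        try:
            lab = np.asanyarray(nib.load(path).dataobj)
        except Exception as exc:
            raise ImageIOError(f"could not read label map {path}: {exc}") from exc
        lab = np.squeeze(lab)
        if lab.ndim == 3:
            if slice_index is None:
                raise UsageError(f"{path} is a label volume; a slice_index is required")
            lab = lab[:, :, slice_index]
    elif fmt == "png":
        import imageio.v3 as iio

        lab = np.asarray(iio.imread(path))
    else:
        raise UsageError(f"label maps must be NIfTI or PNG, got {fmt}")
    lab = np.round(lab).astype(np.int64)

    if not (lab == fossa_label).any():
        raise DataError(f"label {fossa_label} (fossa) absent from {path}")
    if not ((lab == muscle_label).any() or (violation_label is not None and (lab == violation_label).any())):
        raise DataError(f"label {muscle_label} (muscle) absent from {path}")

    muscle = lab == muscle_label
    if violation_label is not None:
        muscle |= lab == violation_label
    fossa = lab == fossa_label
    if muscle_implies_fossa:
        fossa |= lab == muscle_label
    masks = RegionMasks(fossa=fossa, muscle=muscle)
    return masks.require_valid(ground_truth=ground_truth)


def write_label_map(path: str | Path, masks: RegionMasks, fossa_label: int = FOSSA_LABEL,
                    muscle_label: int = MUSCLE_LABEL, violation_label: int = VIOLATION_LABEL) -> None:
    """Write masks as an integer label map (inverse of :func:`read_label_map`)."""
    path = Path(path)
    lab = np.zeros(masks.fossa.shape, dtype=np.int16)
    lab[masks.fossa] = fossa_label
    lab[masks.muscle & masks.fossa] = muscle_label
    lab[masks.muscle & ~masks.fossa] = violation_label
    if _infer_format(path) == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(lab, affine=np.eye(4)), path)
    else:
        write_slice(path, lab.astype(np.uint8))


def read_grades(path: str | Path) -> pd.DataFrame:
    """Read a grade sidecar CSV with columns ``source_id, grade``; validates grades."""
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = {"source_id", "grade"} - set(df.columns)
    if missing:
        raise DataError(f"grade sidecar {path} lacks columns {sorted(missing)}")
    for g in df["grade"]:
        GradeLabel(int(g))
    df["grade"] = df["grade"].astype(int)
    return df
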