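"""Leakage-safe training-set augmentation: flip x2 and 5-stage brightness matching.

The corpus is ranked by whole-image mean intensity and split into five
near-equal brightness stages; each stage's reference is the per-bin mean of
its members' 256-bin histograms.  A training case is expanded tenfold:
{original, left-right flip} x {histogram-matched to each of the 5 stage
references}.  Masks ride along untouched by brightness operations and
mirrored by the flip.  Stage statistics are computed on training folds only,
and every derived case records its provenance so validation leakage is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, UsageError
from .imaging_io import GrayscaleSlice, RegionMasks

N_STAGES_DEFAULT = 5


@dataclass
class AnnotatedCase:
    """A slice with its region masks — the unit the trainer consumes."""

    slice: GrayscaleSlice
    masks: RegionMasks
    case_id: str
    provenance: dict = field(default_factory=dict)

    @property
    def parent_id(self) -> str:
        return self.provenance.get("parent_id", self.case_id)


@dataclass
class BrightnessStage:
    """One of the corpus brightness strata."""

    stage_index: int  # 1-based
    member_ids: list[str]
    reference_histogram: np.ndarray  # per-bin mean over members


def _image_histogram(slc: GrayscaleSlice) -> np.ndarray:
    return np.bincount(slc.pixels.ravel(), minlength=256).astype(np.float64)


def flip_lr(case: AnnotatedCase) -> AnnotatedCase:
    """Mirror image and masks about the vertical axis; toggles laterality."""
    lat = {"left": "right", "right": "left"}.get(case.slice.laterality, "unknown")
    slc = GrayscaleSlice(np.fliplr(case.slice.pixels), source_id=case.slice.source_id,
                         laterality=lat, metadata=dict(case.slice.metadata))
    masks = RegionMasks(fossa=np.fliplr(case.masks.fossa), muscle=np.fliplr(case.masks.muscle))
    prov = dict(case.provenance)
    prov["parent_id"] = case.parent_id
    prov["flipped"] = not case.provenance.get("flipped", False)
    return AnnotatedCase(slice=slc, masks=masks, case_id=f"{case.case_id}#flip",
                         provenance=prov)


def assign_brightness_stages(corpus: list[AnnotatedCase],
                             n_stages: int = N_STAGES_DEFAULT) -> list[BrightnessStage]:
    """Rank by mean intensity, split into *n_stages* quantile groups.

    Ties in mean intensity resolve stably by case id, so the assignment is
    deterministic for any corpus ordering.
    """
    if len(corpus) < n_stages:
        raise UsageError(f"corpus of {len(corpus)} too small for {n_stages} stages")
    order = sorted(corpus, key=lambda c: (float(c.slice.pixels.mean()), c.case_id))
    chunks = np.array_split(np.arange(len(order)), n_stages)
    stages = []
    for i, idx in enumerate(chunks, start=1):
        members = [order[j] for j in idx]
        hists = np.stack([_image_histogram(m.slice) for m in members])
        stages.append(BrightnessStage(
            stage_index=i,
            member_ids=[m.case_id for m in members],
            reference_histogram=hists.mean(axis=0),
        ))
    return stages


def histogram_match(slc: GrayscaleSlice, reference_histogram: np.ndarray) -> GrayscaleSlice:
    """Monotone CDF-to-CDF remap of the whole image onto a reference histogram."""
    ref = np.asarray(reference_histogram, dtype=np.float64)
    if ref.ndim != 1 or ref.size != 256:
        raise UsageError(f"reference histogram must have 256 bins, got {ref.shape}")
    if ref.sum() <= 0:
        raise UsageError("reference histogram is empty")
    src = _image_histogram(slc)
    src_cdf = np.cumsum(src) / src.sum()
    ref_cdf = np.cumsum(ref) / ref.sum()
    levels = np.arange(256, dtype=np.float64)
    lut = np.floor(np.interp(src_cdf, ref_cdf, levels) + 0.5).astype(np.uint8)
    out = lut[slc.pixels]
    return GrayscaleSlice(out, source_id=slc.source_id, laterality=slc.laterality,
                          metadata=dict(slc.metadata))


def augment_training_fold(fold_cases: list[AnnotatedCase],
                          stages: list[BrightnessStage]) -> list[AnnotatedCase]:
    """Expand each training case to 2 (flip) x n_stages (brightness) derived cases.

    *stages* must come from :func:`assign_brightness_stages` on the training
    corpus only; each derived case's provenance records parent, flip and stage.
    """
    if not stages:
        raise UsageError("no brightness stages supplied")
    out: list[AnnotatedCase] = []
    for case in fold_cases:
        for flipped in (False, True):
            base = flip_lr(case) if flipped else case
            for stage in stages:
                matched = histogram_match(base.slice, stage.reference_histogram)
                prov = {"parent_id": case.case_id, "flipped": flipped,
                        "stage_index": stage.stage_index}
                out.append(AnnotatedCase(
                    slice=matched, masks=base.masks,
                    case_id=f"{case.case_id}#f{int(flipped)}s{stage.stage_index}",
                    provenance=prov,
                ))
    return out


def augmentation_manifest(cases: list[AnnotatedCase]) -> pd.DataFrame:
    """Per-derived-case provenance table (derived_id, parent_id, flip, stage)."""
    return pd.DataFrame([
        {
            "derived_id": c.case_id,
            "parent_id": c.parent_id,
            "flip": bool(c.provenance.get("flipped", False)),
            "stage_index": c.provenance.get("stage_index", 0),
        }
        for c in cases
    ])


def assert_no_leakage(augmented: list[AnnotatedCase], validation_ids: set[str]) -> None:
    """Raise if any augmented case derives from a validation image."""
    leaked = {c.parent_id for c in augmented} & set(validation_ids)
    if leaked:
        raise DataError(f"validation images leaked into training augmentation: {sorted(leaked)}")
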