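"""Synthetic scapular-Y-view phantoms with known truth.

No public dataset of annotated Y-view shoulder MRI exists, so every module
here is exercised on generated phantoms: a smooth convex-ish "fossa" region,
a geometrically similar "muscle" region inside it occupying a controlled
fraction of the fossa (the occupation ratio), clustered bright specks inside
the muscle emulating intramuscular fat at an exact pixel fraction, bright
distractor blobs outside the fossa standing in for neurovascular structures
of fat-like signal, and additive truncated Gaussian noise.  The fossa ring
outside the muscle is rendered at fat-like intensity, as in a T1 image where
the atrophied fossa fills with fat.

Geometry is expressed in image-relative units so the same spec renders at
512 px (the native clinical matrix) or at toy sizes for network tests.  All
randomness flows from the single ``seed`` through one generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError, UsageError
from .imaging_io import GrayscaleSlice, RegionMasks, write_label_map, write_slice


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters plus the truth they imply.

    ``fat_intensity_levels`` optionally replaces the single fat level by
    several intensity stages (one per fat cluster), emulating degenerated
    tissue whose fat is "expressed in several stages" and has unclear
    boundaries; the plain two-level phantom keeps it ``None``.
    """

    image_size: int = 512
    occupation_ratio_true: float = 0.6
    fat_fraction_true: float = 0.2
    muscle_intensity_mean: int = 90
    fat_intensity_mean: int = 190
    intensity_sd: float = 0.0
    background_intensity: int = 20
    n_distractors: int = 3
    n_fat_clusters: int = 6
    fat_intensity_levels: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.occupation_ratio_true <= 1.0):
            raise UsageError(f"occupation_ratio_true must be in (0,1], got {self.occupation_ratio_true}")
        if not (0.0 <= self.fat_fraction_true < 1.0):
            raise UsageError(f"fat_fraction_true must be in [0,1), got {self.fat_fraction_true}")
        if self.fat_intensity_mean <= self.muscle_intensity_mean:
            raise UsageError("fat must be brighter than muscle (T1 white-fat convention)")
        if self.image_size < 32:
            raise UsageError("image_size must be >= 32")


@dataclass
class PhantomCase:
    """A generated slice with its ground truth."""

    slice: GrayscaleSlice
    masks: RegionMasks
    fat_mask_true: np.ndarray
    spec: PhantomSpec

    @property
    def case_id(self) -> str:
        return self.slice.source_id


def _radial_region(size: int, center: np.ndarray, base_radius: float,
                   harmonics: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Boolean mask of a star-convex region r(theta) = scale * base * (1 + perturbation)."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - center[0]
    dx = xx - center[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    bound = np.ones_like(theta) * base_radius
    for k, (a, phase) in enumerate(harmonics, start=2):
        bound *= 1.0 + a * np.cos(k * theta + phase)
    return r <= scale * bound


def _fit_muscle_scale(size, center, base_radius, harmonics, fossa_area, target_area):
    """Bisect the similarity scale so the muscle mask hits *target_area* pixels."""
    lo, hi = 0.0, 1.0
    best = None
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        m = _radial_region(size, center, base_radius, harmonics, scale=mid)
        a = int(m.sum())
        if best is None or abs(a - target_area) < abs(best[1] - target_area):
            best = (m, a)
        if a < target_area:
            lo = mid
        else:
            hi = mid
        if a == target_area:
            break
    return best[0]


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom; deterministic given ``spec.seed``.

    The muscle area matches ``occupation_ratio_true x fossa area`` to the
    nearest pixel the bisection can reach (well within 2% relative), and
    exactly ``round(fat_fraction_true x muscle area)`` muscle pixels are
    reassigned to fat intensity, grown as clusters around random seeds.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    center = np.array([size * 0.5, size * 0.5]) + rng.uniform(-0.03, 0.03, 2) * size
    base_radius = size * rng.uniform(0.30, 0.34)
    # low-order radial harmonics keep the outline smooth and convex-ish
    harmonics = np.column_stack([rng.uniform(0.02, 0.08, 3), rng.uniform(0, 2 * np.pi, 3)])

    fossa = _radial_region(size, center, base_radius, harmonics)
    fossa_area = int(fossa.sum())
    if fossa_area == 0:
        raise DataError("degenerate fossa geometry")

    target_muscle = int(round(spec.occupation_ratio_true * fossa_area))
    muscle = _fit_muscle_scale(size, center, base_radius, harmonics, fossa_area, target_muscle)
    muscle &= fossa
    muscle_area = int(muscle.sum())
    if muscle_area < 16:
        raise DataError("muscle region infeasibly small for this spec")
    rel_err = abs(muscle_area - target_muscle) / max(target_muscle, 1)
    if rel_err > 0.02:
        raise DataError(f"could not fit muscle area within 2% (got {rel_err:.3f})")

    # --- clustered fat specks: the n_fat target pixels nearest to random seeds
    n_fat = int(round(spec.fat_fraction_true * muscle_area))
    fat = np.zeros((size, size), dtype=bool)
    cluster_id = np.full((size, size), -1, dtype=np.int32)
    if n_fat > 0:
        midx = np.flatnonzero(muscle.ravel())
        k = max(1, min(spec.n_fat_clusters, n_fat))
        seeds = rng.choice(midx, size=k, replace=False)
        seed_mask = np.zeros(size * size, dtype=bool)
        seed_mask[seeds] = True
        dist, (iy, ix) = ndimage.distance_transform_edt(
            ~seed_mask.reshape(size, size), return_indices=True
        )
        d = np.where(muscle, dist, np.inf).ravel()
        order = np.argsort(d, kind="stable")  # deterministic tie-break by index
        chosen = order[:n_fat]
        fat.ravel()[chosen] = True
        nearest = np.ravel_multi_index((iy, ix), (size, size))
        seed_rank = {s: i for i, s in enumerate(seeds)}
        cid = np.vectorize(lambda s: seed_rank.get(s, -1))(nearest.ravel()[chosen])
        cluster_id.ravel()[chosen] = cid

    # --- intensity rendering
    img = np.full((size, size), float(spec.background_intensity))
    img[fossa] = spec.fat_intensity_mean  # fat-filled fossa ring
    img[muscle] = spec.muscle_intensity_mean
    if n_fat > 0:
        if spec.fat_intensity_levels is None:
            img[fat] = spec.fat_intensity_mean
        else:
            levels = np.asarray(spec.fat_intensity_levels, dtype=float)
            per_cluster = levels[np.arange(int(cluster_id.max()) + 1) % len(levels)]
            img[fat] = per_cluster[cluster_id[fat]]

    # --- distractors: fat-bright blobs outside the fossa, near its boundary
    outside = ~ndimage.binary_dilation(fossa, iterations=2)
    for _ in range(spec.n_distractors):
        ang = rng.uniform(0, 2 * np.pi)
        rad = base_radius * rng.uniform(1.15, 1.35)
        cy = center[0] + rad * np.sin(ang)
        cx = center[1] + rad * np.cos(ang)
        blob_r = max(2.0, size * rng.uniform(0.008, 0.02))
        yy, xx = np.mgrid[0:size, 0:size]
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= blob_r**2
        img[blob & outside] = spec.fat_intensity_mean

    if spec.intensity_sd > 0:
        img = img + rng.normal(0.0, spec.intensity_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    slc = GrayscaleSlice(img, source_id=f"phantom-{spec.seed:08d}",
                         laterality="right", metadata={"synthetic": True})
    masks = RegionMasks(fossa=fossa, muscle=muscle).require_valid(ground_truth=True)
    return PhantomCase(slice=slc, masks=masks, fat_mask_true=fat, spec=spec)


def fi_to_grade_bin(fi_pct: float) -> int:
    """Map a true fatty-infiltration percentage to a Goutallier-like ordinal bin.

    Cut points follow the per-grade means reported for the quantifier on
    clinical data (0.06, 4.7, 20, 43, 56): bin edges at 1, 10, 30 and 50%.
    """
    for g, hi in enumerate((1.0, 10.0, 30.0, 50.0)):
        if fi_pct < hi:
            return g
    return 4


def generate_cohort(
    n: int,
    coupling: Literal["independent", "negative"] = "negative",
    seed: int = 0,
    image_size: int = 512,
    intensity_sd: float = 5.0,
    outlier_fraction: float = 0.08,
    **spec_overrides,
) -> list[PhantomCase]:
    """Generate *n* phantoms whose true (occupation ratio, fat fraction) pairs
    are either independent or negatively coupled.

    The negative mode emulates the clinical relationship between atrophy and
    fatty infiltration: OR ~ U(0.35, 0.95) and
    ``fat = clip(0.55 * (0.95 - OR) / 0.60 + N(0, 0.05), 0, 0.6)``,
    plus an ``outlier_fraction`` of off-trend cases (high OR with high fat,
    and low OR with low fat) as seen in clinical scatter plots.
    """
    if n < 2:
        raise UsageError("cohort needs n >= 2")
    rng = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    for i in range(n):
        u = rng.uniform()
        if coupling == "independent":
            occ = rng.uniform(0.35, 0.95)
            fat = rng.uniform(0.0, 0.6)
        elif coupling == "negative":
            if u < outlier_fraction / 2:  # high-high outlier
                occ = rng.uniform(0.75, 0.95)
                fat = rng.uniform(0.35, 0.55)
            elif u < outlier_fraction:  # low-low outlier
                occ = rng.uniform(0.35, 0.50)
                fat = rng.uniform(0.0, 0.05)
            else:
                occ = rng.uniform(0.35, 0.95)
                fat = float(np.clip(0.55 * (0.95 - occ) / 0.60 + rng.normal(0, 0.05), 0.0, 0.6))
        else:
            raise UsageError(f"unknown coupling {coupling!r}")
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(image_size=image_size, occupation_ratio_true=float(occ),
                           fat_fraction_true=float(fat), intensity_sd=intensity_sd,
                           seed=case_seed, **spec_overrides)
        cases.append(generate_phantom(spec))
    return cases


def save_case(case: PhantomCase, out_dir: str | Path) -> dict:
    """Write PNG + NIfTI label map + JSON truth sidecar; returns the manifest row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cid = case.case_id
    write_slice(out_dir / f"{cid}.png", case.slice)
    write_label_map(out_dir / f"{cid}_labels.nii.gz", case.masks)
    truth = asdict(case.spec)
    truth["muscle_area"] = case.masks.muscle_area
    truth["fossa_area"] = case.masks.fossa_area
    truth["fat_pixels"] = int(case.fat_mask_true.sum())
    (out_dir / f"{cid}_truth.json").write_text(json.dumps(truth, indent=2, default=list))
    fi_true = 100.0 * case.spec.fat_fraction_true
    return {
        "case_id": cid,
        "occupation_ratio_true": case.spec.occupation_ratio_true,
        "fat_fraction_true": case.spec.fat_fraction_true,
        "grade_bin": fi_to_grade_bin(fi_true),
    }


def save_cohort(cases: Sequence[PhantomCase], out_dir: str | Path) -> pd.DataFrame:
    """Save every case and a cohort manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    rows = [save_case(c, out_dir) for c in cases]
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
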