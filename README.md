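# fatquant

Computer-assisted quantification of supraspinatus muscle **atrophy** and
**fatty infiltration** from scapular Y-view shoulder MRI.

Atrophy and fatty infiltration of the supraspinatus are key prognostic
factors for rotator-cuff tears, but in the clinic both are read manually:
atrophy as the **occupation ratio** (muscle area / fossa area on the
Y-view slice) traced by hand, and fat as the ordinal Goutallier grade
(0 none … 4 more fat than muscle), a subjective call with modest
inter-rater reliability. `fatquant` is aimed at musculoskeletal-imaging
researchers who want these indices computed objectively and reproducibly:

- **Occupation ratio** from paired fossa/muscle masks (manual, ITK-SNAP
  style, or predicted): `OR = |muscle| / |fossa|`.
- **Fatty infiltration** by *region-restricted adaptive Otsu thresholding*:
  inside the muscle ROI only, Otsu's threshold t maximises the between-class
  variance ω₀ω₁(μ₀−μ₁)² on the 256-bin ROI histogram and
  `FI = 100 · |{ROI pixels > t}| / |ROI|`. When the ROI intensity SD ≥ 35
  gray levels (severe, multi-stage fat degeneration) the ROI is
  histogram-equalised first — the adaptive gate that stabilises severe cases
  without washing out mild ones.
- **Segmentation evaluation**: Dice, accuracy/sensitivity/specificity,
  and the signed relative area difference.
- **A fully convolutional segmentation network** (truncated-VGG19 encoder,
  15 conv + 5 pool layers, three fully convolutional head layers, pool-3/
  pool-4 skip fusion) with a leakage-safe 10-fold cross-validation harness
  and the flip × 5-stage-brightness (×10) training augmentation, trainable
  at toy scale on CPU.
- **Cohort statistics**: ANOVA + Bonferroni across grades, Pearson OR–FI
  correlation, weighted κ and ICC(2,1) reliability.
- **Synthetic phantoms** with exactly known occupation ratio and fat
  fraction, so every stage is testable without patient data.

See `docs/methods.md` for the full model description and conventions.

## Worked example

```python
import fatquant as fq

# a 256x256 synthetic Y-view with known truth
spec = fq.PhantomSpec(image_size=256, occupation_ratio_true=0.55,
                      fat_fraction_true=0.22, intensity_sd=6.0, seed=42)
case = fq.generate_phantom(spec)

res = fq.quantify_fat(case.slice, case.masks.muscle, sd_gate=None)
print(f"occupation ratio  : {fq.occupation_ratio(case.masks):.3f}")
print(f"ROI SD            : {res.roi_sd:.1f} gray levels")
print(f"Otsu threshold    : {res.threshold}")
print(f"fatty infiltration: {res.fatty_infiltration_pct:.1f} %")
```

prints

```
occupation ratio  : 0.550
ROI SD            : 41.9 gray levels
Otsu threshold    : 116
fatty infiltration: 22.0 %
```

The measured occupation ratio equals the planted 0.550 and the Otsu
threshold (116) falls in the gap between muscle (~90) and fat (~190)
intensities, recovering the planted 22% fat fraction exactly. With the
default adaptive gate instead of `sd_gate=None`, this ROI (SD 41.9 ≥ 35)
would be equalised first and read 53.4% — the stabilising behaviour meant
for severely degenerated, multi-stage fat, which on a clean two-level
phantom trades accuracy for robustness; the gate exists precisely because
real severe tissue is not two-level.

The same pipeline from the shell:

```bash
fatquant phantom -n 20 --size 256 --seed 1 --out cohort/
fatquant fi --image cohort/<id>.png --labels cohort/<id>_labels.nii.gz --out fi.json
fatquant pipeline --cases cohort/ --out results/     # OR + FI + stats per cohort
fatquant eval --gt gt_labels.nii.gz --pred pred_labels.nii.gz --out report.csv
fatquant train -n 8 --k 4 --size 64 --epochs 60 --out run/
```

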