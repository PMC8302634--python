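# Methods

`fatquant` quantifies two radiological indices of supraspinatus muscle
degeneration on the scapular Y-view MRI slice: the **occupation ratio**
(muscle area / fossa area, an atrophy index) and the **fatty infiltration
percentage** (share of muscle-ROI pixels classified as fat). This note
describes the models and procedures, the parameters that matter, what the
synthetic phantoms do and do not emulate, and the numerical conventions.

## Intensity scale and I/O

All analysis operates on integer gray levels 0–255. Scanner data of deeper
bit depth is normalised per slice, by default with a min–max map
`round((v − min) · 255 / (max − min))` (round half up); a percentile-clipping
variant (`percentile(p_lo, p_hi)`) is available for data with hot outliers.
Already-8-bit sources pass through unchanged. No acquisition standard fixes
this mapping, so it is a package convention: the thresholding statistics
below (the SD gate in particular) are only comparable across slices if the
8-bit mapping is fixed and reproducible.

Label maps follow the ITK-SNAP idiom (one integer label per pixel; default
1 = fossa, 2 = muscle). Because the muscle is annotated inside the fossa, the
muscle label implies fossa membership on reading; a third label (3) encodes
predicted muscle pixels outside the predicted fossa so that predictions with
containment violations round-trip exactly and the violation count is always
reportable. Ground-truth masks are validated to have zero violations; the
tolerance is configurable. Areas are pixel counts; the two indices are
same-slice ratios, so pixel spacing cancels and no physical-space resampling
is performed.

## Fatty infiltration by region-restricted adaptive Otsu thresholding

Within the muscle mask only:

1. Compute the population standard deviation σ of the ROI intensities.
2. If σ ≥ `sd_gate` (default 35 gray levels), histogram-equalise the ROI in
   place: each ROI pixel value v maps to `round(255 · CDF(v))` where the CDF
   is computed from ROI pixels only. Pixels outside the mask are never
   touched; the mapping is monotone.
3. Select Otsu's threshold t on the 256-bin ROI histogram by exhaustive
   search: t maximises the between-class variance
   σ²_B(t) = ω₀ω₁(μ₀ − μ₁)², with class 0 = levels ≤ t, class 1 = levels
   \> t, σ²_B = 0 when a class is empty, ties resolved to the lowest t.
4. Classify ROI pixels strictly above t as fat;
   FI = 100 · (fat pixels / ROI pixels).

**The SD gate.** Severely degenerated muscle expresses fat at several
intensity stages with unclear boundaries; a single Otsu cut then lands
between fat sub-levels and underestimates. Equalising the ROI first
stabilises the threshold there. For mildly affected muscle the same
operation is destructive: equalisation makes the ROI's cumulative mass
uniform, after which Otsu splits near the median and reads ~50% regardless
of truth (the wash-out regime). The gate value 35 is a documented clinical
calibration (grade-2 ROIs averaged SD 28.47 with upper limit ≈ 35.95;
grade-3 averaged 35.18), not recomputed here; it is configurable and
`sd_gate=None` disables equalisation entirely. Both regimes are verified on
phantoms: on severe multi-level-fat phantoms the gated quantifier beats the
ungated one by ≈ 11 pp of absolute error, while on near-fat-free phantoms
always-equalising costs ≈ 50 pp.

**Degenerate and unimodal ROIs.** Two guards make fat-free muscle read 0%
rather than ~50%:

- a single-intensity ROI returns that intensity as the threshold (no pixel
  lies strictly above it);
- an ROI whose best split has low separability — Otsu's effectiveness
  η = σ²_B(t)/σ²_T below `min_separability` (default 0.70) — is declared
  fat-free and the threshold is set to the ROI maximum.

The η guard is the package's realisation of the clinically observed
behaviour that no-fat muscle yields near-zero FI (grade-0 readings of
0.06 ± 0.14% on patient data) even though plain Otsu provably mid-splits a
unimodal noise histogram. 0.70 sits between the closed-form η of a unimodal
Gaussian (2/π ≈ 0.64) and that of a 5% fat admixture at an 80-level
intensity gap with SD-10 noise (≈ 0.83). Both the value and the guard itself
are configurable (`min_separability=0` disables it). Known limitation: fat
fractions ≲ 2–3% at realistic noise produce η in the ambiguous band and may
be read as 0.

The binary rendering convention is white (255) = fat, black (0) = muscle.

## Segmentation metrics

For a ground-truth/prediction mask pair: DSC = 2|A∩B|/(|A|+|B|) (1 if both
masks are empty, a flagged vacuous-agreement convention; DSC > 0.70 is
reported as excellent agreement per the usual convention); accuracy,
sensitivity and specificity are percentages from the pixel-wise confusion
matrix over the full image frame (empty denominators yield NaN, never a
silent 0); RAD = 100 · (|A_gt| − |A_pred|)/|A_gt| is signed — positive means
the prediction underestimates — with an unsigned variant by flag. The signed
default follows from cohort reports whose RAD standard deviation dwarfs the
mean, which is impossible for a non-negative statistic. RAD is antisymmetric
under argument swap only up to the changed denominator.

## Synthetic phantoms

Each phantom is a star-convex "fossa" (smooth low-order radial harmonics
around a jittered centre, base radius 0.30–0.34 of the image side), with a
geometrically similar "muscle" inside it whose similarity scale is bisected
until the pixel area hits `occupation_ratio_true × fossa area` (within 2%
relative, typically to the pixel). Exactly `round(fat_fraction_true ×
muscle area)` muscle pixels are reassigned to fat intensity, chosen as the
pixels nearest to a small set of random cluster seeds (clustered specks, not
salt noise, so equalisation behaviour on degenerated tissue is exercisable);
an optional list of fat intensity levels assigns one stage per cluster to
emulate multi-stage degeneration. The fossa ring outside the muscle renders
at fat intensity (an atrophied fossa fills with fat on T1), the background
is dark (20), and bright distractor blobs outside the fossa stand in for
neurovascular structures of fat-like signal; distractors never touch the
muscle. Additive Gaussian noise (SD `intensity_sd`, rounded, clipped to
[0, 255]) is applied last. All randomness flows from one seed through a
single generator; identical specs are bit-identical.

Defaults: 512×512 (the native clinical matrix; smaller sizes for network
toys), muscle intensity 90, fat intensity 190, 3 distractors, 6 fat
clusters. Cohorts couple the true parameters either independently or
negatively — OR ~ U(0.35, 0.95),
fat = clip(0.55·(0.95 − OR)/0.60 + N(0, 0.05), 0, 0.6) — with an 8% share of
off-trend outlier cases (high-OR/high-fat and low-OR/low-fat), emulating the
clinically observed strong negative OR–FI relationship with scattered
outliers.

What the phantoms do **not** emulate: scapular anatomy, partial-volume
boundaries, bias fields, Rician noise statistics, multi-slice context, or
inter-annotator variability. Passing phantom tests therefore demonstrates
algorithmic correctness (truth recovery, invariances, leakage safety), not
clinical accuracy on patient MRI.

## Augmentation and cross-validation

Training corpora are ranked by whole-image mean intensity and split into
five near-equal quantile stages (ties stable by case id); each stage's
reference is the per-bin mean of its members' 256-bin histograms. A training
case expands tenfold: {original, left–right flip} × {histogram-matched to
each of the five stage references}. Histogram matching is the monotone
CDF-to-CDF table `lut(v) = round(interp(CDF_src(v), CDF_ref, levels))`.
Masks are untouched by brightness operations and mirrored by the flip; the
flip toggles laterality metadata and is an involution. Whether the original
brightness staging used equal-count quantiles or fixed intensity ranges is
not documented anywhere; quantiles are the reproducible choice here.

Fold splitting shuffles ids with a seeded generator into k folds whose sizes
differ by at most one (240 ids, k = 10 → ten folds of 24; training folds of
216 expand to 2160). Stage statistics are computed per fold on that fold's
training images only, validation folds stay original, and an audit asserts
that no validation id appears in any derived case's provenance.

## Segmentation network

A fully convolutional network maps a 1-channel H×W slice to 2-channel H×W
per-pixel scores (fossa, muscle). The default encoder follows the VGG19
channel progression (64-128-256-512-512) truncated to 15 convolutions in
five blocks with five 2×2 max poolings; a 16-convolution variant restores
full VGG19 behind `vgg19_variant=True`. Three fully convolutional head
layers follow the deepest pooling, and the decoder fuses the pool-3 and
pool-4 feature maps with the upsampled head output through learned
transposed convolutions (bilinear-seeded; FCN-8s-style ×2, ×2, ×8), so input
sizes must divide 32. The two output channels are non-exclusive sigmoids
trained with per-pixel binary cross-entropy: the muscle lies inside the
fossa, so exclusive softmax labels would be ill-posed. Optimiser (Adam,
lr 2e-3 for the toy runs), loss, epochs and initialisation are package
choices — no training recipe is documented for the original clinical model,
whose weights are unavailable; clinical-scale performance numbers are
therefore out of scope here. The implementation is a compact numpy
CPU engine (im2col convolution, adjoint-based transposed convolution,
manual backpropagation) and is exactly reproducible from seeds.

The standing toy experiment (`toy_cv_experiment`): 8 noiseless 128×128
phantoms with OR ~ U(0.45, 0.9) and fat ~ U(0, 0.35) (mild-to-moderate
disease), a small config (8-16-16-24-24 channels, one convolution per
block), 4-fold CV, 350 epochs. It reaches mean validation DSC ≈ 0.94
(fossa ≈ 0.98, muscle ≈ 0.90) in about two CPU minutes and is an engineering
sanity gate for the harness — extreme-fat phantoms, where most of the muscle
is bright fat locally identical to the fossa ring, make muscle segmentation
a pure context task and are deliberately excluded from this gate.

## Cohort statistics

FI across Goutallier grades: one-way ANOVA followed by Bonferroni post hoc
pairwise t tests (p multiplied by the number of comparisons, capped at 1),
with per-grade mean, SD and observed min/max as the lower/upper limits
(range, not a CI — the original table layout does not define them; a CI
option is labelled as such). OR–FI association: Pearson's r with the
two-sided t-based p. Rater agreement: weighted Cohen's κ on the 5×5 grade
table (linear weights by default, quadratic by flag, scheme echoed in
output) and ICC(2,1) (two-way random effects, single measure, absolute
agreement — the model is echoed in output). ANOVA/t/Pearson are computed via
scipy.stats, κ via scikit-learn, ICC via pingouin; all are verified against
hand-computed textbook fixtures, and a permutation experiment checks ANOVA's
type-I calibration.

## Problem sizes in the standing checks

The test suite and `scripts/acceptance.py` use 256×256 phantoms for the
FI-recovery grids (60 phantoms per noise condition), 512×512 for the
50-phantom occupation-ratio cohort, 256×256 for the 100-phantom
end-to-end correlation cohort, a 240-case corpus for the augmentation/fold
arithmetic, and the 128×128 toy network experiment above; one forward pass
of the full 512×512 architecture verifies the shape contract. These sizes
are the package's validation conditions; the generator accepts any size
≥ 32 with sides divisible by 32 for the network.
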