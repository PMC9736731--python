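# Methods

This note documents the models, parameter choices and numerical
conventions behind `stromatex`, and what the synthetic benchmarks do and
do not demonstrate.

## Stain model and color deconvolution

Staining follows the Beer–Lambert model: a pixel's optical density
`OD_c = −log₁₀(I_c / I0_c)` is a non-negative linear combination of unit
per-stain OD vectors. `stromatex.stains` implements the forward model
(`density_to_rgb`, with round-half-up 8-bit quantization), and the
inverse (`rgb_to_od` + `od_to_density`), i.e. Ruifrok–Johnston color
deconvolution. Conventions:

* intensities are clamped to ≥ 1 before the log, so a fully dark pixel
  has finite OD `log₁₀(255) ≈ 2.41`;
* negative density solutions (noise, off-model colors) are clipped to 0;
* stain matrices are validated for non-negativity, unit row norms and a
  condition number below 1e8.

The trichrome preset models three stains — hematoxylin, aniline blue,
Biebrich scarlet/acid fuchsin — with OD vectors chosen so that each
renders its expected hue *and* the matrix stays well conditioned
(cond ≈ 12.5). Conditioning matters because 8-bit rounding noise in OD
space is amplified by `‖(Vᵀ)⁻¹‖`; with this preset the noiseless
synthetic tiles are recovered at ≈ 0.007 OD RMSE, comfortably under the
0.02 OD design target. Hematoxylin and aniline blue are both blue-ish
dyes, so their vectors are inherently correlated; presets that push them
closer together degrade recovery quadratically. The hematoxylin channel
is computed but deliberately not analyzed — the texture panel uses the
blue (mature collagen) and red (cytoplasm/young matrix) channels only.

Densities are mapped to 8-bit gray for texture analysis on a **fixed
global scale** (`gray = round(255·min(d, D_max)/D_max)`, `D_max = 2.0`
OD). Per-image normalization would destroy absolute staining-intensity
differences, which are themselves a reported class of differential
features.

## Texture panel (212 features per tile)

Per channel: 1 mean intensity + 45 SFTA + 30 Gabor mean-squared energy +
30 Gabor mean amplitude = 106 features; blue block then red block.

**SFTA decomposition.** The channel image is partitioned by `n = 8`
multi-level Otsu thresholds. The 15 binary masks are the 7 band masks
`t_i < g ≤ t_{i+1}` plus the 8 upper masks `g > t_i` (the top band
coincides with the last upper mask, hence `2n − 1`). Each mask
contributes (border fractal dimension, area in pixels, mean gray
intensity). The mask border is the mask minus its 3×3 erosion; the
fractal dimension is the least-squares slope of `log N(s)` vs
`log(1/s)` over dyadic box sizes `s = 2 … min(H,W)/2`. Conventions for
degenerate input: empty mask or empty border → feature triple (0, 0, 0);
a constant image (unthresholdable) yields 45 zeros with a logged
warning, never an exception in batch runs. Area is reported as a raw
pixel count, comparable across tiles because the tile size is fixed.

Multi-level Otsu is solved exactly by dynamic programming over the
256-bin histogram (`O(k·B²)`), minimizing total within-class variance —
equivalent to the usual between-class-variance maximization, but
tractable at 8 thresholds where combination-enumeration implementations
are not. Tests cross-check the partition against
`skimage.filters.threshold_multiotsu` at 2 thresholds and against
exhaustive search on coarse histograms.

**Gabor bank.** 5 wavelengths (2–32 px, octave spaced) × 6 orientations
(0°–150°, 30° steps), bandwidth 1 octave, unit aspect ratio, complex
kernels from `skimage.filters.gabor_kernel` made DC-free by mean
subtraction (a constant tile responds exactly zero). Responses use FFT
convolution with reflect padding; features are the per-pixel mean
squared magnitude and mean magnitude, wavelength-major. Because the
bank covers 180° at 30° steps with isotropic envelopes, rotating a tile
by 90° permutes orientation responses exactly; mean intensity and SFTA
areas/means are exactly rotation invariant (fractal dimensions shift
minutely through box-grid alignment).

## Differential screening

Features are z-scored with the pooled mean/SD over all observations
(ddof 1); pooling preserves every ANOVA F statistic, so z-scoring is a
presentation step, not an inferential one. Zero-variance features are
excluded with a warning rather than propagated as NaN. Each remaining
feature is tested by classical one-way ANOVA (no Welch correction) and
declared significant at the Bonferroni level `α₀/m` (α₀ = 0.05, m = 212
for the full panel → 2.36 × 10⁻⁴ per test). Tukey–Kramer pairwise
comparisons (studentized-range critical value `q(α, k, N−k)`; Kramer's
harmonic-mean adjustment for unequal group sizes) run on the
ANOVA-significant features only, mirroring the ANOVA-then-post-hoc
protocol; a flag disables gatekeeping. For three-group screens the
result also tabulates which features are significant in which pairwise
contrast (a Venn-style summary).

Null calibration (in tests and the acceptance script): with independent
null features the Bonferroni family-wise error is
`1 − (1 − α₀/m)^m ≈ α₀`, and Tukey–Kramer's family-wise error is α by
construction; Monte-Carlo estimates over seeded simulations fall within
3 MC standard errors of these nominal levels.

## COL11A1 classifier

A Random Forest (500 trees, √m features per split, unlimited depth,
fixed seed, defaults chosen as common practice and fully exposed in
config) is trained on all 212 features of the labeled discovery tiles.
Ties in the majority vote break toward negative. Feature importance is
mean impurity decrease.

The confusion matrix is reported under two conventions, because
published matrices sometimes normalize by predicted class: the textbook
reference-denominator rates TP/(TP+FN), TN/(TN+FP), and the
predicted-denominator rates TP/(TP+FP), TN/(TN+FN) (precision and NPV
relabeled). The shipped worked example reconstructs an integer matrix
from a printed validation description — 54 predicted positive with
70.37% of them correct, 97 predicted negative with 71.13% correct —
giving TP=38, FP=16, TN=69, FN=28 and accuracy 107/151 = 70.86%; those
printed rates are consistent with predicted-class denominators (the
reference-denominator rates for the same matrix are 57.6%/81.2%).
Core-level prediction (`predict_cores`) calls a core positive when any
of its tiles is, mirroring any-positive-cells manual scoring.

## TMA quantification

Per-cell tables carry type (fibroblast / epithelial / immune),
compartment (stroma / cancer), per-marker mean DAB OD and a CD8 flag.
Core summaries report type percentages over all cells; CAF-subset
percentages as the strictly-greater-than-threshold marker-positive share
among all fibroblasts (default DAB threshold 0.3 OD per marker —
thresholds are study-specific settings, exposed in config, and the
synthetic DAB mixture model places its two modes >3 SD from this
default); CD8⁺ percentages within each compartment separately. A core
with fewer than 200 epithelial cancer cells is flagged invalid and
excluded from all downstream statistics (the rule is applied uniformly
to composition, CAF-subset and CD8 quantities). Tumor-level values are
medians over valid cores (midpoint for even counts); per-quantity
missing values (e.g. CAF share in a fibroblast-free core) are reported
as missing, never as zero, and skipped in the median. Patients lacking a
usable value for any sample of the matched triplet are excluded from
topography tallies, with the exclusion listed.

## Immune topography

A compartment is INFILTRATED when its CD8⁺ share exceeds 2% strictly;
exactly 2% maps to NOT_INFILTRATED (the boundary is undefined in the
protocol being modeled, so the package documents strict inequality and
makes the threshold configurable). The (stroma, cancer) pair maps
bijectively to HOT / EXCLUDED / HOT_CANCER / COLD. Pattern tallies over
ordered (primary, metastasis, recurrence) triplets always sum to the
number of analyzable patients.

## Synthetic data: what it emulates, and what it does not

Fibers are constant-width random-walk strokes: initial heading ~ von
Mises(κ), per-step heading increments ~ Normal(0, curvature), width
uniform in a range, stamped as disks and contributing additive stain
density once per fiber. This is the simplest model controlling the
three properties that distinguish the phenotypes — width, curvature,
alignment:

| parameter | thin-linear (COL11A1⁺-like) | thick-curly (COL11A1⁻-like) |
|---|---|---|
| width range (px) | 1–3 | 6–12 |
| curvature (rad/step) | 0.02 | 0.3 |
| orientation κ | 4.0 (aligned) | 0 (isotropic) |
| fibers per tile | 40 | 12 |
| stain mix (blue, red) | (0.55, 0.35) | (0.80, 0.08) |

The stain mixes encode that COL11A1⁺ ECM stains with a blue/red mixture
while COL11A1⁻ ECM stains primarily with aniline blue. Width ranges are
disjoint by construction, and an independent skeleton/distance-transform
oracle confirms the rendered widths separate. Tiles are 200×200 px,
background density 0.05, Gaussian density noise SD 0.02 (clipped at 0)
— fiber geometry parameters are free choices made once for plausibility
and separability, not biological measurements. Default set sizes mirror
the study design: 100+/99− discovery tiles, 151 validation tiles, 42
patients × 3 samples × 3 cores.

Cell tables draw types from multinomial fractions; fibroblasts sit in
stroma, epithelial cells in the cancer compartment, immune cells split
between them (default 50/50). DAB intensities follow a two-mode normal
mixture (positive ≈ N(0.60, 0.10), negative ≈ N(0.08, 0.04), clipped at
0) so the default threshold recovers marker-positive fractions in
expectation. CD8 positivity is assigned to immune cells at a rate that
reproduces the target per-compartment CD8 share. Cohort simulation
draws infiltration status once per (patient, sample) — primary tumors
are stroma-infiltrated less often (p = 0.6) than metastatic/recurrent
ones (p = 0.85) — with core-level jitter, mimicking triplicate punches
of one block.

What passing these benchmarks shows: the pipeline's operations are
correct on data exactly obeying their assumptions, with exact ground
truth. What it does not show: performance on real histology — no
nuclei, no scanner/stain variation between slides, no spatial cell
clustering, no fiber branching or crimp, and perfectly separable
phenotype classes (the synthetic Random-Forest accuracy of ~100% is a
correctness check of the workflow, not a claim about real-tissue
accuracy). Reproducibility is by construction: every generator is a
pure function of (spec, seed), with per-object seeds derived from the
master seed through a documented `SeedSequence((master, index))` scheme.

## Problem sizes in tests and the acceptance script

Null-screen calibration uses 20 seeded repetitions of 10+10
same-phenotype tiles; Monte-Carlo FWER estimates use 1000–2000
simulations; the classifier benchmark uses the full default set sizes
(199 discovery / 151 validation tiles); bit-reproducibility is checked
on reduced runs. These sizes were chosen so each check retains clear
statistical resolution (3-SE Monte-Carlo bands) at modest runtime.

## Known limitations

* Stain vectors and `I0` are a fixed preset; no Macenko/NMF stain-vector
  estimation or inter-slide normalization, so intensity features depend
  on the preset.
* Box-counting dimensions depend mildly on box-grid alignment; only
  rotation invariance of areas/means is exact.
* ANOVA treats tiles/tumors within a group as exchangeable; no
  mixed-effects correction for multiple tiles per core or patient.
* The epithelial-count QC rule gates all quantities uniformly; protocols
  that gate only composition statistics would need the configurable
  threshold relaxed per analysis.
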