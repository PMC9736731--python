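# stromatex

Quantitative analysis of extracellular-matrix (ECM) remodeling in the
ovarian-cancer tumor microenvironment from standard histology.

High-grade serous ovarian carcinoma (HGSOC) metastases remodel their
stroma: activated cancer-associated fibroblasts (CAFs) expressing
collagen XI alpha-1 (COL11A1) deposit thin, linearized collagen fibers,
while COL11A1-negative stroma keeps thick, curly fibers. `stromatex`
implements the computational side of a tissue-microarray (TMA) study of
this process, for image-analysis and tumor-microenvironment researchers:

1. **Stain separation** — Masson's trichrome RGB tiles are converted to
   per-stain density images by Beer–Lambert color deconvolution: with
   unit stain OD vectors as rows of `V`, per-pixel densities solve
   `d = (Vᵀ)⁻¹ · OD`, `OD_c = −log₁₀(max(I_c, 1)/I0_c)`.
2. **Texture panel** — 106 features per stain channel (aniline blue and
   Biebrich scarlet), 212 per tile: 1 mean staining intensity; 45 SFTA
   features (15 binary masks from 8-level multi-Otsu thresholding, each
   contributing border box-counting fractal dimension `D = dlogN/dlog(1/s)`,
   stained area, and mean intensity); 30 Gabor mean-squared-energy and 30
   mean-amplitude features from a 5-wavelength × 6-orientation bank.
3. **Differential screening** — pooled z-scoring, one-way ANOVA per
   feature, Bonferroni correction at α = 0.05/212, Tukey–Kramer
   post-hoc pairwise comparisons.
4. **COL11A1 prediction** — a seeded Random Forest trained on discovery
   tiles predicts COL11A1 positivity of validation tiles; the confusion
   matrix reports sensitivity/specificity under both the reference-class
   and predicted-class denominator conventions.
5. **TMA quantification** — per-cell tables (as exported by a cell
   detection tool) are summarized into core- and tumor-level cell-type
   percentages, DAB-thresholded CAF-subset fractions (COL11A1⁺, α-SMA⁺,
   PDPN⁺ among fibroblasts), with a <200-epithelial-cell QC rule and
   median aggregation over triplicate cores.
6. **Immune topography** — per-compartment CD8⁺ fractions are
   thresholded at 2% to call stroma/cancer infiltration and map each
   tumor to HOT / COLD / EXCLUDED / HOT-CANCER; infiltration patterns
   are tallied across matched primary/metastasis/recurrence triplets.

Because no imaging data is publicly deposited for such cohorts, the
package ships a first-class synthetic-data module: fiber-texture tiles
with exact density ground truth rendered through the same forward stain
model the deconvolution inverts, TMA layouts (42 patients × 3 samples ×
3 cores = 378 cores by default), and per-core cell tables with known
composition. Every stage runs end to end with no download.

## Worked example

```bash
python examples/03_differential_screen.py
```

```
tested m = 212 features at per-test alpha = 0.000236
significant features: 172
top 5 by F statistic:
  red_sfta_band5_mean_int            F =    2343.1  p = 1.54e-28
  red_gabor_amp_w2_d120              F =    2102.9  p = 6.88e-28
  ...
```

15 thin-linear (COL11A1⁺-like) and 15 thick-curly (COL11A1⁻-like) tiles
are simulated, deconvolved and screened: 172 of 212 texture features
differ significantly after Bonferroni correction — the two fiber
architectures are strongly separable. The other example scripts cover
stain-separation fidelity (`01`, recovery RMSE ≈ 0.008 OD), the panel
itself (`02`), classifier training and both confusion-matrix conventions
(`04`), and cohort quantification with CD8 topography tallies (`05`).

A thin CLI mirrors the library (`stromatex simulate|deconvolve|features|
diffstats|train|predict|evaluate|quantify|topography|run-discovery|
run-cohort`); run `stromatex --help` for details.

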