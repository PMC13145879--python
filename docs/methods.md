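# Methods

`leafcode` reimplements, end to end, an image-based pipeline for
testing whether folk (ethnotaxonomic) leaf categories of the ayahuasca
vine *Banisteriopsis caapi* can be recovered by machine learning from
photographs of dried herbarium leaves. The original study's images are
not publicly distributed, so the package ships a deterministic
synthetic-leaf generator that reproduces the study's *sampling design*
(10 classes, 47 plants, 384 leaves, 768 two-surface images) and its
qualitative class structure; every downstream stage is exercised and
tested against that generator.

## Pipeline

1. **Segmentation.** Each photograph shows a leaf on a bright
   herbarium sheet. We threshold the channel
   `B' = 0.5·S + 0.5·(1 − G/255)` (S = HSV saturation, G = green
   channel) with Otsu's method: sheets are bright and unsaturated
   (low B'), dried leaves darker and more saturated whether green or
   browned (high B'). Cleanup is a 3×3 closing, the largest connected
   component and hole filling, so cracks in dried tissue cannot split
   the mask. A run fails loudly if the foreground covers < 1% of the
   frame. The mask is cropped with an 8 px margin and rescaled so the
   longer side is 512 px (bilinear image, nearest-neighbor mask).

2. **Descriptors** (105 named values per image, all computed strictly
   over the mask):
   - *Color* (18): per-channel mean and population SD in sRGB, HSV and
     CIELab. Hue uses circular statistics (mean direction, circular SD
     in degrees) because dried leaves sit near the 0°/360° wrap. The
     Lab transform decodes sRGB with the standard piecewise 2.4-exponent
     curve and uses the D65 matrix row sums as the white point, so pure
     white maps to (100, 0, 0) exactly.
   - *Shape* (7): Hu moment invariants of the binary silhouette,
     log-scaled as `h'ᵢ = −sign(hᵢ)·log₁₀(|hᵢ| + 1e−30)`.
   - *GLCM* (6): contrast, dissimilarity, homogeneity, energy, ASM and
     correlation of a symmetric, normalized co-occurrence matrix,
     averaged over distances {1, 2, 4} × angles {0°, 45°, 90°, 135°}.
     Gray levels are 16 equal-width bins on the masked min–max range
     with occupied bins compacted to consecutive ranks; compaction
     makes a two-tone image land on adjacent levels, matching direct
     pair-enumeration arithmetic. Only pairs with both pixels in the
     mask are counted. A zero-variance marginal defines correlation 1.
   - *LBP* (10): uniform local binary patterns, P=8, R=1, bilinear
     neighbors, tie rule neighbor ≥ center; bins 0–8 by popcount for
     uniform codes, bin 9 for the rest; centers restricted to pixels
     whose full 3×3 neighborhood is inside the mask. Note the
     interpolated operator is exactly invariant to *affine* intensity
     maps but not to arbitrary monotone maps.
   - *HOG summary* (18): the bounding-box crop is resampled to
     128×128; unsigned gradients, 9 orientation bins, 16×16 cells,
     per-cell L2 normalization (ε = 1e−6); we report the mean and SD
     of each orientation bin across cells, keeping the feature count
     independent of image size.
   - *Gabor* (24): 4 orientations × 3 frequencies (0.05, 0.15, 0.30
     cycles/px), σ = 0.56/f; masked mean and SD of response magnitude.
   - *Canny density* (1): edge pixels inside the mask / mask area,
     σ = 1, hysteresis thresholds at the 70th/90th percentile of the
     masked gradient magnitude.
   - *Edge operators* (12): Sobel, Scharr (±3/±10), Prewitt gradient
     magnitude and |4-neighbor Laplacian|; masked mean, SD and energy,
     excluding a 1-pixel rim so every 3×3 support stays inside the
     leaf.
   - *Fourier* (9): power fractions in 8 equal radial bins up to
     Nyquist plus the power-weighted spectral centroid, computed on
     the mean-subtracted, background-zeroed 128×128 crop.

   Convolutional families (HOG, Gabor, Canny, Fourier) first replace
   the background with the masked mean so no sheet pixel can leak
   through a filter support; this makes every one of the 105 values
   bit-invariant to background edits, which the suite asserts.

3. **Classification.** Six classifiers mirror the roster of a
   Weka-style workbench. Two are explicit functional stand-ins that we
   specify exactly rather than emulate numerically: `knn_local`
   (per-query adaptive k ≤ 15 chosen by a 3× median-1NN-spacing
   radius, inverse-distance votes) and `knn_weighted` (k tuned once
   per training split by leave-one-out accuracy over 1..20, smallest k
   on ties). The rest are standard: a 500-tree random forest; an
   "optimized" forest that keeps the top ⌈p/2⌉ features ranked by a
   preliminary 200-tree forest's impurity importance and refits; a
   one-vs-rest RBF SVM (C = 10, γ = 1/p on z-scored features) whose
   probability scores are a softmax over decision values (a
   deliberate, documented Platt-free surrogate); and a one-hidden-layer
   (64 ReLU) MLP standing in for a generic deep-learning component.
   Evaluation is stratified 10-fold cross-validation; the scaler and
   the forest's feature selection are fit on the training split only.
   Ties everywhere break on alphabetical class order, and all
   stochastic fits are seeded, so results are bit-reproducible.

   Surface modes: per-image `adaxial` and `abaxial` tables, and two
   combined readings — `combined_concat` (one row per leaf, both
   surface vectors concatenated; the default "combined" mode) and
   `combined_pool` (all images stacked). The instance unit for
   combined analysis is the leaf; folds do **not** respect plant
   identity by default, mirroring the original protocol (some classes
   have a single plant, so plant-atomic folds are impossible there),
   but `group_aware=True` provides plant-atomic folds for leakage
   analysis and is recommended whenever the design allows it.

4. **Statistics.** The replicate unit is the per-fold support-weighted
   F-measure (10 values per classifier × surface). We run one-way
   ANOVAs across classifiers within each surface and across surfaces
   pooling classifiers, reporting F, p, η² = SSB/SST and
   ω² = (SSB − df_b·MSW)/(SST + MSW) floored at zero; Tukey–Kramer
   pairwise tests use q = |Δmean|/√(MSW/n_h) with the harmonic pair
   size and the studentized-range distribution; mean F-measures get
   t-based 95% confidence intervals. ROC areas are support-weighted
   one-vs-rest Mann–Whitney statistics on the probability scores.

5. **Confusion structure.** The pooled confusion matrix is
   row-normalized to percentages (full precision retained; integer
   rounding only at render time) and drawn as a heatmap. The
   similarity network has classes as nodes and undirected edges
   weighted by the symmetric error frequency
   `w_ij = (C_ij + C_ji)/(n_i + n_j)`; zero-weight edges are omitted.
   The source text describing the original network is contradictory
   about whether edges encode errors or correct classifications; we
   adopt symmetric error frequency and keep raw counts available so
   any alternative weighting is recomputable. Layout is seeded
   Fruchterman–Reingold with edge weights as spring strengths, so more
   confused classes land closer together.

## The synthetic generator

Each class is a `ClassConfig`: base CIELab color, per-channel
plant-level color jitter (default SD 1.5; leaf-level effects are half
that, encoding the plants ≫ leaves sampling hierarchy), lamina shape
(aspect ratio, apex sharpness, margin roughness), surface value-noise
texture (frequency, amplitude), pinnate vein density/contrast, and an
abaxial delta (lighter by 6 L* units, 1.4× vein contrast — dried
abaxial surfaces are paler with more prominent venation). The lamina is
a superellipse with a sharper apex half and sinusoidal margin
perturbation, composited on a beige vignetted sheet at 600×400 px;
per-leaf aspect receives ~5% multiplicative jitter so outline is a
noisy cue, not a class label. The default ten classes reproduce the
study's per-class (plants, leaves) counts exactly: (1,17), (4,30),
(11,88), (1,31), (9,63), (2,25), (3,16), (11,80), (3,18), (2,16).

Two structures are planted deliberately. `cabi_like`/`quebrador_like`
share texture, shape and veins and sit ~2 ΔE apart in color — inside
the jitter level, so they are genuinely confusable, and their mutual
confusion should dominate the similarity network.
`hybrid_like`/`arara_like`/`outgroup_like` sit ≥ 20 ΔE from every
other class and should classify near-perfectly. Class color/texture
parameter values are engineering choices (the source study publishes
no quantitative per-class statistics to calibrate against); they were
fixed once from field-realistic dried-leaf Lab ranges.

What the generator does *not* emulate: photographic shading and
specularities, real venation topology, leaf curling/folding, sheet
labels and annotations, and inter-feature correlations of real tissue.
Passing the recovery tests therefore demonstrates that the pipeline's
plumbing, descriptors, evaluation and statistics behave correctly and
that planted signal/overlap propagate end to end — not that the
descriptors would achieve any particular accuracy on real herbarium
images.

A damage model removes an apical fraction (severity in (0, 0.5]) of
the mask, repainting it with sheet color and flagging the record
non-intact; non-intact rows are excluded from feature tables by
default, mirroring intact-leaf curation. The default damage rate is 0;
a curation demo can set ~0.3 to exercise the filter.

## Numerical and design notes

- Population (not sample) SDs in all descriptors; sample SD in the
  t-intervals (an estimator, not a descriptor).
- Degenerate guards: empty masks and < 8 px silhouettes are errors;
  constant images give defined values (GLCM correlation 1, zero HOG,
  zero Canny density, all-zero Fourier outputs) rather than NaNs;
  zero-variance features z-score to 0.
- Gabor responses use edge-replicate padding so a constant image has
  exactly zero masked response SD.
- An ideal symmetric step edge peaks identically on two adjacent
  columns, so Canny marks a 1–2 px band there; this is a property of
  non-maximum suppression on synthetic ties, not of real images.
- `make_folds` deals each shuffled class round-robin with a global
  counter (per-class fold counts differ by ≤ 1); group-aware mode
  assigns whole plants greedily to the smallest fold within each
  class. Classes smaller than k are allowed with a warning.
- MLP early stopping needs a stratifiable 10% split; on training sets
  with < 40 rows or a class with < 4 members it falls back to plain
  500-epoch training instead of crashing.
- Problem sizes in the test suite: oracle-equivalence tests run 50
  seeds per family on ≤ 32×32 images; the end-to-end recovery test
  uses the full default dataset (768 images) once per session, and
  the planted-overlap network check varies the CV fold seed (5 seeds)
  over that single dataset rather than regenerating images per seed.

## Known limitations

- The original tool's exact extractor defaults live in its source,
  not the paper; numeric feature values are not expected to match it
  bit-for-bit — the pipeline's behavior is what is reproduced.
- Accuracies on the synthetic data are far above the 60–70% reported
  on real herbarium material; the generator's classes are cleaner than
  real folk types by construction.
- Without `group_aware`, same-plant leaves appear in train and test;
  this mirrors the apparent original protocol but inflates accuracy
  whenever plants are distinctive. Both modes are exposed.
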