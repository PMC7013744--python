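# Methods

## Problem setting

Breast-ultrasound computer-aided diagnosis pipelines extract texture
features from small regions of interest (ROIs) and classify them as
malignant (invasive ductal carcinoma, IDC) or benign (breast
mouse / fibroadenoma, BM). A practical complication is that the same
lesion imaged under different scanner parameter presets (depth, dynamic
range, gain, gray map, frame averaging, ...) yields systematically
different images, so a feature subset tuned on one preset can fail on
another. This package implements *universal* feature selection: it
searches for one subset of texture features that classifies well — and
consistently — under every acquisition setting simultaneously.

The unit of analysis is a 23×23-pixel block tiled from a radiologist-
outlined ROI (only blocks fully covered by the ROI mask are used). Each
physical block is observed once per setting; the observations share a
`pair_id`. The clinical dataset behind the original study (23 patients,
four presets of one scanner, ≈4,000 blocks) is private, so this package
ships synthetic generators that emulate its statistical structure, and
the published per-setting accuracy tables as reference inputs for
summary arithmetic.

## The texture bank (126 features)

Nine families, concatenated in a fixed order (F1–F126):

1. **Histogram (F1–F7)** — energy Σp² and entropy −Σp·log₂p of the
   normalized gray-level histogram, plus mean, variance, SD, skewness
   and kurtosis of the pixel distribution. Skewness and kurtosis use
   population moments; kurtosis is excess (m₄/m₂² − 3); both are defined
   as 0 for a constant block. All entropies in the package are base 2.
2. **Gray-level co-occurrence / spatial dependence (F8–F20)** — a
   symmetric normalized co-occurrence matrix at distance 1 is built per
   angle {0°, 45°, 90°, 135°}; the 13 classic statistics (correlation,
   difference entropy/variance, sum average/entropy, sum of squares,
   sum variance, contrast, energy, entropy, local homogeneity, cluster
   shade and prominence) are computed per angle and averaged. Sum
   variance is taken about the sum average. Correlation is defined as 0
   when a marginal SD vanishes (constant input).
3. **Statistical feature matrix dissimilarity (F21)** — mean absolute
   gray-level difference over the four unit displacements, averaged.
4. **Run lengths (F22–F26)** — maximal equal-level runs per direction
   (same four directions); short/long-run emphasis, gray-level and
   run-length uniformity, run percentage; averaged over directions.
5. **Laws texture energy (F27–F36)** — five 5×5 masks built as outer
   products of L5 = (1,4,6,4,1), E5 = (−1,−2,0,2,1), S5 = (−1,0,2,0,−1):
   LE, EL, SL, EE, LS (first letter = row vector). The block is
   convolved (valid region only); the mean and population variance of
   the absolute response are the features. Every mask contains a
   zero-sum factor, so all ten features vanish on constant input.
6. **Neighbouring gray-level dependence (F37–F41)** — for each interior
   pixel, the count k of its 8 neighbours whose level matches within
   tolerance a = 0; Q(g, k) is summarized by small/large number
   emphasis, number non-uniformity, second moment Σ(Q/S)² and entropy.
   k = 0 cells carry no inverse-square mass in the small-number
   emphasis (the emphasis sums over k ≥ 1).
7. **Neighbourhood gray-tone difference (F42–F46)** — per-level sums
   s(g) of |g − neighbourhood mean| over interior pixels; busyness,
   coarseness, complexity, contrast and textural strength in the
   classic forms, with ε = 10⁻⁶ guarding denominators that vanish on
   homogeneous input (a constant block has coarseness 1/ε).
8. **Wavelet domain (F47–F94)** — a one-level 2-D orthonormal Haar DWT
   with symmetric boundary extension produces the LL subband (23×23 →
   12×12); families 1–6 are re-applied to the subband after min–max
   re-quantization to 32 levels, and the raw subband mean and SD are
   kept as F73/F74. The LL subband must be at least 5×5 for its Laws
   features, so full extraction requires blocks of at least 9×9.
9. **Local Fourier (F95–F126)** — for each interior pixel the 8
   neighbours are read clockwise from east and the unnormalized 8-point
   DFT is taken; the features are the means and SDs (over interior
   pixels) of the 8 magnitudes and 8 phase angles. Phases live in
   (−π, π]; the phase of a zero coefficient is 0, and negligible
   real/imaginary components (below 10⁻⁹ relative to the coefficient
   magnitude) are snapped to zero first so that exactly-real negative
   coefficients get a deterministic phase of +π.

Matrix families (2, 3, 4, 6, 7) operate on a min–max quantization of the
block to 32 gray levels (bin edges divide [min, max] evenly, top edge
inclusive, constant blocks map to level 0); histogram, Laws and local
Fourier features use the raw levels. 32 levels is standard texture
practice; it keeps the 32×32 co-occurrence matrices well populated on
23×23 blocks.

## Filter stage

Tables are samples × features with `setting_id`, `pair_id` and class
labels. Three scores rate each feature i across the S settings
(sample, n−1, standard deviations throughout; dispersion denominators
below 10⁻¹² are replaced by 10⁻¹² and the feature flagged
`degenerate_dispersion` — a legitimately zero dispersion means perfect
cross-setting consistency and is rewarded, not an error):

* **Augmented Sorensen-Dice ratio** — Σ_groups (x̄_g − x̄)² over
  Σ_groups s²_g. Two orientations exist: grouping by *setting*
  (the literal multi-dataset form; `dice_score`'s default) measures how
  much a feature's level moves between presets, and grouping by *class*
  is the classic Fisher-discriminant score. The candidate-pool ranking
  uses the class orientation, since the filter's job is to discard
  features carrying no diagnostic signal; the setting orientation is
  structurally blind to class structure in any class-balanced design.
* **t-score** — the absolute Welch two-sample statistic
  |x̄⁺ − x̄⁻|/√(s⁺²/n⁺ + s⁻²/n⁻) per setting, aggregated as
  (Σ_j T_j) / (S · SD(T_1..T_S)). The aggregation rewards features that
  discriminate strongly *and* uniformly across settings. A variant with
  a squared numerator is available (`ttest_form="squared_numerator"`);
  the standard form is the default.
* **Paired Pearson score** — the correlation of the feature between two
  settings over pair-matched blocks, |r| averaged over partner
  settings, then aggregated with the same sum/(S·SD) rule. Pairs
  missing in either setting are dropped from that pairwise term only;
  zero variance on either side yields r = 0.

Features are ranked per metric (descending); list A holds the `top_n`
(default 40) by mean rank over the three metrics, list B the `top_n` by
single-feature cross-validated SVM accuracy (mean over settings). The
candidate pool is A ∩ B; if the intersection falls below a floor
(default 5), the union truncated to `top_n` by aggregate rank is used
and flagged in the report.

## Wrapper stage

Features are z-scored (sample SD; constant features map to 0 and are
flagged) with parameters learned on the selection split only. The GA
then evolves binary chromosomes over the candidate pool:

* **Fitness** of a subset = Σᵢ Acc_Sᵢ − Σ_{i<j} (Acc_Sᵢ − Acc_Sⱼ)²,
  where Acc_Sᵢ is the subset's stratified 5-fold cross-validated SVM
  accuracy in setting i. The penalty term makes the fitness, at a fixed
  accuracy total, maximal exactly when all settings agree — the formal
  statement of "universality".
* **Operators** — roulette-wheel selection proportional to fitness
  (shifted so the minimum is non-negative when negative values occur;
  all-zero totals fall back to uniform), two-point crossover with
  probability 0.65, independent bit flips at rate 0.03, and — when an
  exact subset size k is requested — a repair operator that clears or
  raises uniformly random bits to restore exactly k ones. Defaults:
  population 500, 500 generations, elitism of 1 (the best-ever
  chromosome survives each generation, making the best-fitness history
  non-decreasing). One seeded generator drives initialization and all
  operators; fitness reports are cached by bit pattern, so duplicate
  chromosomes cost nothing.
* **SVM** — soft-margin RBF machine, f(x) = sgn(Σ αᵢdᵢK(xᵢ,x) + b) with
  K(x,x′) = exp(−‖x−x′‖²/2σ²). C = 1 by default; σ² defaults to half
  the median squared pairwise distance of the training split (the
  median heuristic). The quadratic program is solved by scikit-learn's
  SVC; the package owns the kernel-width convention, the explicit dual
  decision form (verified against the solver in tests) and the seeded
  stratified folds.

The end-to-end pipeline splits the table 50/50 by `pair_id`
(class-stratified, seeded) so that all settings of a physical block stay
on one side; scaling, filtering and the GA use the selection half, and
the chosen subsets are re-scored on the held-out half. Cardinalities 5,
10 and 15 are searched as separate constrained runs.

## Synthetic data

`generate_feature_table` draws paired multi-setting tables directly at
the feature level: within-class variance 1 per feature, decomposed into
an additive latent pair effect (SD 0.8, shared by all settings of a
pair — this is what makes the paired correlation informative) and
per-setting noise (SD 0.6). Universal informative features separate the
class means by `effect_size` (default 2) within-class SDs in every
setting; setting-specific ones only in theirs; the rest are pure noise.
Mild per-setting affine transforms of every feature column mimic
preset-dependent feature shifts (all three filter scores are invariant
to them). Defaults: 4 settings, 500 blocks per class per setting —
approximately the study's 4,038 blocks, which do not divide evenly
across four settings.

`generate_texture_dataset` draws two-class textured 23×23 blocks: white
noise smoothed with a class-specific Gaussian kernel (widths 1 and 3
pixels), one base field per pair, passed through each setting's monotone
gain/dynamic-range-compression intensity map and quantized to 8 bits.
Monotone maps preserve pixel rank order across settings (tested via
Spearman correlation ≥ 0.9) — the minimal stand-in for distinct scanner
presets. Neither generator models speckle statistics, attenuation or
other acquisition physics: passing tests demonstrate that the selection
machinery behaves correctly on data with the assumed statistical
structure, not that the clinical accuracies are reproducible.

## Numerical conventions and edge cases

* Logarithms base 2; 0·log 0 := 0.
* Quantization: floor((x − min)/(max − min)·L) clipped to [0, L−1];
  constant input → level 0.
* σ = 0 moments: skewness/kurtosis := 0. Degenerate dispersions in the
  aggregate filter scores: guarded at 10⁻¹² and flagged.
* Coordinates row-major and 0-based; tiles enumerated left-to-right,
  top-to-bottom.
* Fold partition sizes differ by at most 1 (stratified k-fold).
* Determinism: every stochastic component (generators, splits, folds,
  GA) takes an explicit seed, and identical seeds reproduce identical
  reports bit-for-bit.

## Design choices on genuinely open points

* The multi-dataset Dice ratio's two orientations (above); the ranking
  uses the class-discriminative one.
* The t-score numerator: standard absolute difference by default; the
  squared form is a config switch, not the default.
* Low-scoring features are removed by rank cut (`top_n`), not by a
  score threshold.
* The 5/10/15-feature subsets come from separate cardinality-
  constrained GA runs (repair operator), not post-hoc truncation.
* The z-transform is applied as defined even though it does not confine
  values to (−1, 1); no additional squashing is applied.
* The wavelet family keeps both the subband histogram mean/SD (within
  F47–F53) and the raw subband mean/SD (F73/F74); the duplication is
  intentional in the feature numbering and is preserved.

## Scaled-down experiment sizes

The shipped experiments (used by `scripts/acceptance.py` and the
acceptance tests) run at desk scale, chosen once: GA recovery uses 3
planted features among 20, 200 blocks per class per setting, population
30 and 20 generations over 20 seeded runs; the consistency-preference
and chance-level checks use 100–200 blocks per class. The full-size
defaults (population 500, 500 generations, 126 features) remain the
library defaults.

## Known limitations

* The exact formulas behind the original feature-name tables are not
  published; the classic literature forms are used (documented above),
  so absolute feature values need not match the original system's.
* With the search budget scaled down to population 30 × 20 generations
  on a 20-feature pool, the GA's planted-subset recovery rate is
  measured at roughly 0.7–0.85, not 1.0: exhaustive enumeration shows
  the planted subset is the fitness optimum, but roulette selection on
  the narrow fitness range (≈1.9–3.9) exerts weak selection pressure
  and runs can converge on a two-of-three local optimum. The full-size
  budget (500 × 500) does not have this problem on pools of this size
  (it can enumerate the space many times over).
* Single-scanner, two-class, block-level classification only; no
  patient-level aggregation, no probability calibration, no multiple
  testing correction in the filter stage (none is applied by design).
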