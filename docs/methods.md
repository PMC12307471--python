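# Methods

## The refinement model

The package treats a radiomics panel as a cohort matrix `F ∈ R^{n×N}`
(n patients, N features) and refines it in a fixed order: normalize →
entropy profile + relevance filter → entropy weighting → fractal
augmentation → adaptive weighting → redundancy filter → stability filter →
evaluation. Each stage is unsupervised: labels enter only at evaluation.

### Normalization

Each column is affinely mapped to [0, 1]; constant columns map to 0 and are
flagged. Normalization is required for the multiplicative entropy weighting
to be scale-meaningful and makes the α, β, γ defaults transferable across
feature panels. The transform is idempotent on its own output. Missing
values are a hard error everywhere: silently imputing a cell would corrupt
the histogram entropy estimates that drive the whole first stage.

### Entropy weighting and relevance filtering

Per-feature Shannon entropy is estimated from an equal-width histogram with
`entropy_bins` bins (default 64) over [0, 1], probabilities by maximum
likelihood (counts/n, no smoothing — smoothing would destroy the exact
H = 0 of constant features that the filter relies on). Entropy is reported
in bits; the log base cancels in the weighting ratio.

A genuinely open design point is whether the entropy that drives the
weighting is a property of the whole feature set or of each feature. This
package computes a per-feature entropy `H_i` with `H_max = max_i H_i`,
because only a per-feature quantity can differentiate features in the
weighting `f_i ← f_i (H_i/H_max)^α`; a single set-level entropy would scale
all columns identically and select nothing. α ≥ 0 (default 1) tunes how
aggressively low-entropy features are shrunk; α = 0 disables the weighting,
and applying the transform with α₁ then α₂ equals one application with
α₁+α₂. Features with `H_i < entropy_floor` (default 0.5 bits — roughly "a
distribution at least as spread as a 70/30 two-bin split") are dropped with
reason `low_entropy`.

### Fractal augmentation

The box-counting dimension is computed on the patient's binary tumor mask —
the one per-patient spatial object guaranteed to exist — and the same shift
`β·D_f` is added to all of that patient's features (default β = 0.1, so the
shift spans ≈ [0, 0.3] on [0, 1]-scaled features). Box counts use a fixed
grid anchored at the array origin, box edges in voxels, default sizes the
powers of two from 1 to half the smallest array dimension (at least 4
scales required); the dimension is the least-squares slope of log N(ε)
against log(1/ε) over all admissible scales, with the fit R² reported so
poor scaling regimes are visible. The fixed anchor makes N(ε) exactly
non-increasing in ε and the whole estimate deterministic. When no masks
are available (CSV-only input), the stage is a no-op (D_f treated as 0).

### Adaptive weighting

Feature scores `s_i` aggregate patients by the mean (config-swappable to
median); `μ` is the grand mean of the scores, and `W_i = σ(γ(s_i − μ))`
with the logistic σ. Weights are strictly inside (0, 1), equal 0.5 exactly
at `s_i = μ`, and are monotone in the score; raising γ moves every weight
away from 0.5. Default γ = 4 on [0, 1]-scaled features makes weights span
roughly (0.1, 0.9) for typical score spreads. The refined set keeps one
weighted column per feature (`W_i f_i`, element-wise); the literal weighted
sum `Σ_i W_i f_i(p)` — a single scalar per patient — is also emitted as the
`serfe_scalar` audit column, but is not used downstream because collapsing
the panel to one number per patient would leave nothing to classify.

### Redundancy filtering

Features are scanned in descending adaptive weight (ties broken
lexicographically by name) and dropped when |Pearson r| with any
already-retained feature exceeds `redundancy_threshold` (default 0.85), so
the higher-weight member of a correlated group survives. Zero-variance
features, for which r is undefined, are counted redundant by convention.
The redundancy rate is 100 × dropped / candidates. A post-hoc full pairwise
scan of the retained set can verify the guarantee; the test suite does
exactly that as a brute-force oracle.

### Stability filtering

With k repeated extractions per patient (balanced design required;
unbalanced replication is an error rather than a silent reweighting), each
feature's ICC is the one-way random-effects ANOVA estimate:
`σ̂_w² = MS_within`, `σ̂_b² = max(0, (MS_between − MS_within)/k)`,
`ICC = σ̂_b²/(σ̂_b² + σ̂_w²)` with 0/0 → 0. The estimator is invariant to
adding a constant and to common scaling. Features with ICC below
`icc_threshold` (default 0.75, inclusive retention at the threshold) are
dropped; the stability score is the percentage of candidates at or above
the threshold, computed before dropping. When no replicates are provided
the stage is skipped and reported as `not_assessed`, never fabricated.

### Evaluation

Stratified k-fold cross-validation (default 5 folds, fold sizes and class
ratios within one patient of balance) over three classifier families with
deliberately unremarkable, config-exposed defaults: linear-kernel SVM with
C = 1 (ROC score = decision margin), 200-tree random forest (score =
positive-class vote fraction), and 5-NN on standardized features (score =
neighbor vote fraction). Standardization statistics are computed on
training folds only. Metrics are percentages; AUC is the rank-based
(Mann–Whitney) probability that a random positive outranks a random
negative, ties counted ½, computed on pooled out-of-fold scores. One seed
governs fold assignment and classifier randomness; identical inputs and
seed give byte-identical JSON reports (reports contain no timestamps —
timings go to the log stream).

## The image-feature panel

The built-in extractor computes a compact representative panel rather than
a full IBSI battery (the refinement stages are panel-agnostic and accept
any external table):

- first-order: population moments (mean, variance, skewness, excess
  kurtosis — both 0 for constant regions), energy, histogram entropy,
  order statistics;
- GLCM: 3-D co-occurrence over 13 unique directions at distance 1,
  restricted to voxel pairs inside the mask, symmetric and normalized per
  direction, gray levels by equal-width binning of the in-mask range
  (default 16), features averaged over directions with pairs;
- shape: volume (voxel count × voxel volume), surface area by exposed
  voxel-face counting, sphericity `π^{1/3}(6V)^{2/3}/A`, compactness
  `36πV²/A³`, elongation (ratio of second to first principal-axis lengths
  of the mm-scaled mask coordinates);
- spectral entropy: Shannon entropy in bits of the normalized non-DC power
  spectrum of the mean-subtracted in-mask intensity sequence taken in fixed
  C scan order (0 for constant regions).

Face counting is exact for rectilinear shapes (a cube of any size has
sphericity `(π/6)^{1/3} ≈ 0.806`) but converges to 3/2 the analytic area on
smooth surfaces — a digitized ball therefore converges to sphericity 2/3,
not 1. This staircase bias is accepted for determinism and
dependency-freedom and is documented here so shape values are compared only
within the same convention.

## The synthetic cohort generator

`generate_cohort` emulates the statistical structure the filters assume,
with every planted property recorded as ground truth: Gaussian unit-variance
features in equicorrelated blocks (`x = √ρ·z_block + √(1−ρ)·ε`), a
standardized mean shift d on informative columns, planted near-duplicate
blocks (high ρ) as redundancy fodder, near-constant spike columns (a
constant with three outlier patients, ≈ 0.24 bits after normalization) as
relevance-filter fodder, and replicates `base + N(0, σ_w²)` with
`σ_w² = σ_b²(1−ICC)/ICC` so the population ICC is exact under the additive
homoscedastic noise model.

Defaults are fixed at a desk-scale cohort: 100 patients, positive-class
fraction 0.57 (a glioblastoma-vs-other cohort shape), 300 features of which
20 are informative at d = 1.5, generic block correlation 0.6 (below the
redundancy threshold), 10 redundant blocks of 5 at ρ = 0.95, 10 low-entropy
spikes, 3 replicates with stable ICC 0.9 and 15% unstable features at
ICC 0.3. With 20 independent informative features at d = 1.5 the
between-class Mahalanobis separation is ≈ √20·1.5 ≈ 6.7, so near-perfect
classification is expected and observed; chance-level behaviour is checked
separately on d = 0 cohorts.

What the generator does **not** emulate: MRI physics (bias fields, partial
volume, acquisition drift), heavy-tailed or skewed feature marginals,
heteroscedastic or feature-correlated replicate noise, site/scanner batch
structure, and label noise. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated model, not
clinical performance on real cohorts.

## Numerical choices and degenerate inputs

- Entropy: histogram over the fixed range [0, 1]; inputs outside it (beyond
  1e-9) are rejected, directing callers through the normalizer.
- An all-constant matrix (H_max = 0) is a degenerate-profile error, as is a
  relevance filter that would drop every feature.
- Box counting requires ≥ 4 scales (smallest array dimension ≥ 16 for the
  default power-of-two ladder).
- Adaptive weighting of a single feature returns W = 0.5 with a warning.
- Correlation of zero-variance columns, empty precision denominators,
  degenerate F1, all-tied ROC scores: all follow the explicit conventions
  stated above rather than raising.
- Problem sizes in the test and acceptance runs (cohorts of 100–500
  patients, panels of 40–300 features, 512² / 243² / 64³ phantoms, 50-rep
  ICC grids) are the package's chosen desk-scale study conditions; all
  statistical checks are seeded.

## Known limitations

- The fractal stage adds a patient-constant shift; it changes
  between-patient geometry only through D_f differences and is a no-op for
  CSV-only workflows without masks.
- Greedy redundancy retention is order-dependent by design (priority =
  adaptive weight); it guarantees no retained pair above the threshold but
  not a maximum-cardinality such set.
- ICC is the one-way, single-measurement form; two-way models, confidence
  intervals and unbalanced designs are out of scope.
- The built-in panel is representative, not IBSI-complete (no GLRLM, GLSZM,
  NGTDM, wavelet or Gabor families).
- Classifier hyperparameters are fixed defaults; no tuning, calibration or
  model selection beyond the cross-validated comparison.
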