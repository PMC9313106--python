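# Methods

## Scalar maps

FA and MD are computed voxel-wise from the tensor eigenvalues. Scanner
tensor fits can produce negative eigenvalues in noisy voxels, so both
operations first sort the eigenvalues descending and clamp negatives to
zero, logging the fraction of affected voxels; this keeps FA inside [0, 1]
by construction. An all-zero voxel (background) is assigned FA = 0 rather
than NaN so the background never enters the FA histogram support.
Precomputed FA/MD maps can be supplied directly; they are validated against
the same invariants on load.

## Whole-brain ROI

The mask is derived from the FA map by default and reused for the MD map of
the same subject (the two are co-registered by construction). Stages:
Gaussian smoothing (default σ = 1 mm, converted to voxels through the
header spacing), threshold segmentation (Otsu by default; strictly-above
threshold), retention of the largest 26-connected component, and 3-D hole
filling. The largest-component rule is an automated, reproducible
replacement for manual removal of extracranial noise. `clean_mask` is
idempotent, and the result is guaranteed to be a single 26-connected
component with no enclosed cavities.

## Transform bank

The default manifest holds 25 forms. Design choices where the labels alone
under-determine the construction:

* **Wavelet** — one-level orthonormal 3-D Haar decomposition on the mask's
  bounding box, zero-padded to even dimensions. Subbands are kept at
  decimated resolution (spacing doubled) with the mask downsampled by
  strict majority (≥ 5 of 8 voxels per 2×2×2 block). Haar is the simplest
  orthonormal choice and admits an exact Parseval check, which the tests
  assert.
* **Exponential / logarithm** — monotone remaps of the masked intensity
  range. With u = x − min and r = max − min over the mask:
  exponential(x) = exp(u·ln(r+1)/r) − 1 + min and
  logarithm(x) = ln(u+1)·r/ln(r+1) + min. Both preserve the masked minimum
  and range, and are exact mutual inverses (tested as a round trip). The
  shift by the masked minimum is what makes the pair invertible for inputs
  that do not start at zero.
* **Gabor** — applied slice-wise in the axial plane (DTI slices are axial).
  `theta` is the in-plane orientation; `beta` is interpreted as the filter's
  half-response angular bandwidth, which sets the envelope width
  perpendicular to the carrier through
  σ_perp = √(ln2/2)·λ/(π·tan(β/2)); the envelope along the carrier is fixed
  at 0.56λ (one octave) and the wavelength defaults to 4 voxels
  (configurable). The responses are modulus values. The orientation
  convention is pinned by a test: rotating the image 90° swaps the θ = 0 and
  θ = 90 responses exactly.
* **LoG** — Laplacian of Gaussian at σ ∈ {1, 3} mm, converted to voxels per
  axis via the spacing.

The manifest is configuration, not code; only the default must total
25 forms × 92 features = 2300 per map.

## Texture features

Masked intensities are discretized into a fixed **bin count** Ng = 32
(equal-width over the masked min–max, half-open bins with the maximum
closed). A fixed count rather than a fixed width is used because FA is
dimensionless in [0, 1] while transformed volumes have arbitrary ranges;
with the count fixed, rescaling intensities leaves every discretized-matrix
feature unchanged (asserted as a property test).

Matrix conventions:

* GLCM: distance 1, the 13 unique 3-D directions, symmetrized (both orders
  counted) and **pooled across directions before normalization** — pooling
  is more robust than per-direction averaging in thin masks.
* GLRLM: runs scanned along the same 13 directions; features computed per
  direction, then averaged.
* GLSZM: zones are 26-connected components of constant level.
* GLDM: dependence of a voxel = number of its 26-neighbours (in-mask only)
  within α levels; α = 0 by default. Matrix columns are indexed by
  dependence + 1 so small-dependence emphases never divide by zero.

All entropy-type features use the natural logarithm with 0·ln 0 ≡ 0.
Histogram kurtosis is the Pearson (non-excess) ratio m₄/m₂² of population
moments. Features whose formula degenerates to 0/0 on constant regions
(correlation, IMC1, kurtosis, coefficient of variation, …) are emitted as 0
with a logged warning, never NaN, so downstream selection never sees
missing values. The per-class feature lists (23/24/16/16/13) are frozen in
`src/dtiradiomics/data/feature_registry.json`.

Shape/morphology descriptors (volume, surface voxels, bounding box,
elongation/flatness from principal moments) are available through
`shape_feature_set` but are not part of the default 2300-feature vector:
the per-form totals leave no room for them, and with one shared mask their
values would be duplicated verbatim between the FA and MD blocks.

## Feature selection

Stage 1 tests every feature with a two-sample t-test when both class
samples pass a Shapiro–Wilk normality check at 0.05, otherwise a
Mann–Whitney U test (the choice is recorded per feature); survivors have
two-sided p < 0.001, uncorrected. Stage 2 standardizes the training
columns, builds a 100-point geometric λ grid from λ_max (smallest penalty
with an all-zero solution, λ_max = max|xⱼᵀ(y − ȳ)|/n) down to 10⁻⁴·λ_max,
and evaluates each λ by stratified 5-fold cross-validated mean binomial
deviance (per-sample deviance −2[y ln p̂ + (1−y) ln(1−p̂)], fold SEs
reported so the 1-SE rule can also be applied). λ_min minimizes the mean
deviance with ties broken toward the larger (sparser) λ. The penalized
fits use the saga proximal-gradient solver with C = 1/(nλ) — matching the
1/n-scaled L1-penalized logistic objective with an unpenalized intercept —
warm-started along the descending grid, so a whole 100-point path costs
little more than a single fit and near-separable fits at tiny λ stay
cheap. The refit at λ_min uses a tighter tolerance. Folds are stratified
and seeded; the whole selection is bit-reproducible given the seed.

## Radiomic score and evaluation

The final model is an unpenalized maximum-likelihood logistic regression on
the selected (standardized) features. Rad_score is the linear predictor —
log-odds, not the sigmoid — since operating points are naturally annotated
on that scale and AUC is invariant to the monotone sigmoid. Perfect
separation or non-convergence triggers a ridge-stabilized fallback
(L2, C = 100) with a logged warning; the model records which path was
taken. Coefficients are reported on both standardized and original scales.

AUC is the Mann–Whitney concordance (ties counted 1/2); the tests verify it
against trapezoidal integration of the ROC curve to 1e-12. The operating
point maximizes Youden's J with ties broken toward higher specificity.
Demographics: Welch t-test for continuous variables, two-sided Fisher exact
for 2×2 categorical tables.

## Synthetic phantoms

Each subject is an ellipsoidal brain (semi-axes 40×36×26 mm) on a
48×48×32 grid at 2 mm spacing — small enough for minute-scale end-to-end
runs while echoing clinical 2 mm slices. Inside the brain a target FA field
is built as baseline 0.45 + a per-subject offset (SD 0.02) + a unit-variance
Gaussian random field (correlation length 6 mm, amplitude 0.05, per-subject
length jitter 5%). Cases receive a +0.08 FA shift and a 1.5× longer
texture correlation length inside a centred sub-ellipsoid at half the brain
semi-axes. MD is 8×10⁻⁴ mm²/s with 5% relative correlated fluctuation.

The (FA, MD) pair is converted exactly to an axially symmetric eigenvalue
triple via δ = FA/√(3 − 2FA²), λ₁ = MD(1+2δ), λ₂ = λ₃ = MD(1−δ), so the
map-computation stage runs on realistic inputs. Gaussian noise
(SD = 0.02 × baseline MD; Rician optional) is added per eigenvalue inside
the brain only — air voxels stay exactly zero, mimicking scanner-masked
maps; this also exercises the sort-and-clamp policy. Per-subject seeds are
spawned deterministically from the cohort seed.

What the phantoms do **not** emulate: anatomy (no tissue classes, tracts,
or ventricles), partial-volume edges, Rician bias by default, B-matrix or
acquisition effects, and registration error. Passing tests therefore
demonstrate the pipeline's statistical correctness and its ability to
recover planted group differences — not clinical performance on patient
data.

## Problem sizes in the tests

The acceptance tests run the planted-effect end-to-end study at the full
default scale (48×48×32 grid, 25-form manifest, 30/30 train and 26/24
test). The 20-seed null-cohort leakage check keeps the cohort sizes but
uses a 24×24×16 grid and a single-form manifest, since absence of
train/test leakage does not depend on resolution or manifest size; this
keeps the whole suite in the minutes range. Unit tests use a 24×24×16
phantom for the same reason. Oracle-equivalence property tests run on
arrays up to 6×6×6 with up to 4 gray levels, where exhaustive enumeration
is cheap.

## Known limitations

* The exact composition of the original 2300-feature bank is not public;
  the 25 × 92 decomposition reconstructs the printed totals from the named
  transform families and matrix classes, and the registry makes it
  auditable rather than canonical.
* The "beta" parameter of the Gabor labels is not defined anywhere
  upstream; the angular-bandwidth reading documented above is this
  package's choice.
* GLSZM/GLDM feature lists follow common radiomics usage; one
  normalized-nonuniformity variant was omitted from GLDM to keep the
  registry at 13.
* The univariate screen applies no multiplicity correction by design (the
  0.001 cut is the protocol); interpretability of single survivors on real
  data should account for that.
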