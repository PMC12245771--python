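# Methods

## IVIM signal model and segmented fitting

The diffusion-weighted signal of a voxel is modeled as a two-compartment
biexponential,

    S(b) = S0 · [(1 − f)·exp(−b·D) + f·exp(−b·D*)],

where `D` (mm²/s) is the tissue water diffusion coefficient, `D*` (mm²/s)
the pseudo-diffusion coefficient of the capillary network, and `f` the
fraction of signal in the fast compartment. Because `D* ≫ D`, the fast
compartment has decayed essentially to zero above a b-value threshold
(default 200 s/mm², configurable), which yields the standard segmented
estimator:

1. `D` = −slope of the ordinary least-squares line through `ln S` vs `b`
   over `b > 200`; the intercept extrapolated to `b = 0` seeds the
   perfusion fraction as `f₀ = 1 − intercept/S(0)`.
2. With `D` fixed, `(S0, f, D*)` are fitted to the full curve by bounded
   trust-region nonlinear least squares, seeded at `D*₀ = 10·D`.

Parameter boxes are breast-tissue-plausible: `D ∈ [1e-5, 5e-3]`,
`D* ∈ [3e-3, 0.5]` mm²/s, `f ∈ [0, 0.5]`, `S0 ∈ (0, 2·max S]`. The
per-voxel `D*` lower bound is raised to the fitted `D`, so `D ≤ D*` holds
for every converged voxel. Signals are floored at `1e-6 · S(b=0)` before
the log to survive noise nulls. A voxel whose nonlinear step fails is kept
with the monoexponential fallback (`f = 0`, `D*` at its lower bound) and a
cleared convergence flag rather than excluded, so habitat maps stay
complete; convergence fractions are reported per lesion.

On the default 11-point protocol {0, 20, 50, 80, 100, 150, 200, 400, 600,
800, 1000} s/mm² — chosen to cover both regimes the threshold presupposes,
and configurable because acquisition protocols vary — noiseless
biexponential voxels are recovered to ≲0.1 % in `D`, ≲1e-4 absolute in
`f`, and ≲0.1 % in `D*`; residual pseudo-diffusion signal above the
threshold biases `D` by well under 1 % for `f ≤ 0.15`.

## Synthetic data

**DWI phantom.** The default phantom is a 32³ grid (1 mm isotropic) whose
lesion is a 16³-voxel block tiled by four disjoint habitat blocks with
parameters emulating the canonical four-part tumor structure: part 1
(D = 0.8e-3, f = 0.15), part 2 (D = 2.0e-3, f = 0.10), part 3 (D = 1.2e-3,
f = 0.30), part 4 (D = 0.7e-3, f = 0.04); S0 = 1000 everywhere. Blocks
rather than nested ellipsoids keep the subregions contiguous and exactly
disjoint at desk scale; ellipsoid geometries are available. Noise is
Rician — the magnitude of a complex Gaussian perturbation,
`sqrt((S+n₁)² + n₂²)` — as appropriate for magnitude MR data; the default
sigma of 20 gives SNR 50 at b = 0. The generator does not simulate coil
profiles, motion, eddy currents, partial voluming, or spatially correlated
noise, so passing tests demonstrate estimator correctness under the noise
model, not robustness to acquisition artifacts.

**Planted (D, f) mixtures.** Cluster-number and label-recovery experiments
use isotropic 4-component Gaussian mixtures. The components sit on a
square of side 5 within-component SDs — inside the ≥ 4 SD separation
regime in which Calinski-Harabasz K-selection and K-means label recovery
are reliable. At exactly 4 SDs the Bayes-optimal assignment already
misclassifies ≈ 4–5 % of points (adjacent components overlap at 2 SDs per
side), capping the achievable adjusted Rand index near 0.88, so the
recovery guarantees are stated for comfortably separated mixtures.

**Tabular cohorts.** Cohort tables are generated feature-by-feature:
continuous features are standard normal plus a planted standardized mean
shift per positive endpoint; binary conventional-MRI features are
Bernoulli with planted odds ratios on a baseline rate. Labels are balanced
exactly to the stated prevalence. The default 299-lesion cohort uses the
four endpoints at their observed prevalences (HER2 0.32, Ki-67 0.45, HR
0.69, LNM 0.57) with moderate planted effects concentrated in the habitat
and CF families. A replicate table adds Gaussian rater noise (default
scale 0.1 SD) to continuous features only, emulating feature re-extraction
from an independent re-segmentation for ICC testing. A planted
standardized shift `d` yields the binormal univariate AUC `Φ(d/√2)`, which
the calibration experiments use as ground truth.

## Habitat clustering

Per-voxel `(D, f)` vectors are pooled (across lesions by default — this
guarantees that "part 2" means the same thing in every patient; a
per-lesion mode exists) and z-scored per dimension before clustering,
because raw `D` (~1e-3) and `f` (~0.1) differ by two orders of magnitude
and unstandardized Euclidean K-means would ignore `D` entirely. K-means
uses k-means++ seeding with 10 restarts and a fixed seed. The cluster
count is chosen over K = 2..8 by the Calinski-Harabasz score
`[BSS/(K−1)] / [WSS/(n−K)]` (ties → smallest K; all-point-mass clusters
return an infinite sentinel). On fitted phantom data at SNR 50 the
within-habitat spread of `(D̂, f̂)` reaches ~2 SDs of separation and the CH
curve flattens instead of peaking — K selection by CH needs either lower
noise or better-separated tissue classes; the analysis scripts report the
curve as measured and then cluster at the four-part structure.

For K = 4 the centroids are mapped deterministically to canonical parts:
part 2 = highest centroid `D`; part 3 = highest `f` among the rest;
part 4 = lowest `D + f` (in standardized coordinates) among the rest;
part 1 = the remainder; ties break by `f` then `D`. For K ≠ 4 the fallback
is lexicographic `(D, f)` order. Assignment labels each in-mask voxel with
the canonical part of its nearest centroid in standardized space.

## Radiomic features

Whole-tumor extraction z-scores each source map (D and f by default; D*
and S0 optional) over the VOI, discretizes by equal-frequency binning
(default 32 bins — a balance of histogram resolution against small
subregions; the bin edges sit at empirical quantiles, ties to the lower
bin), and computes 16 first-order statistics (percentiles interpolate
linearly between order statistics; variance, skewness, and kurtosis use
population moments, kurtosis non-excess; entropy in bits and uniformity
come from the discretized histogram), 13 GLCM statistics (symmetric
co-occurrence at distance 1, counts summed over the 13 unique 3D
directions before normalization), and 6 shape descriptors (volume; surface
area of the marching-cubes boundary mesh, since voxel-face counting
overstates curved surfaces by ~50 %; sphericity; maximum 3D diameter from
boundary-voxel pairs; elongation and flatness as √-eigenvalue ratios of
the coordinate covariance). GLSZM/GLRLM/NGTDM/GLDM families and filtered
images are deliberately out of scope (reduced texture family).

Habitat extraction reports, per canonical part, the volume, volume
fraction, and the first-order statistics of the **raw** D and f
intensities restricted to the part. Per-part z-normalization would zero
out exactly the part-level statistics the method interprets (the median D
of the high-D part, etc.), so normalization is a whole-tumor preprocessing
step only. Absent parts yield zero features plus an absence flag column;
parts under 10 voxels are computed but flagged unstable.

## Feature filtering, model search, evaluation

Robustness: features whose ICC(2,1) — two-way random effects, absolute
agreement, single measure, computed from the ANOVA mean squares — across
the primary and replicate tables falls below 0.75 are dropped. Redundancy:
a seeded greedy pass removes one random member of every surviving pair
with |Pearson r| > 0.99. Whole-tumor families (large) are additionally
pre-selected by LASSO over 10 log-spaced alphas in [5e-3, 5e-2] chosen by
cross-validated prediction error; small families skip this step.

The model search crosses four selectors (RFE by iterative
smallest-|coefficient| elimination of an L2 logistic model; Kruskal-Wallis
and ANOVA rankings; Relief nearest-hit/nearest-miss margins), two
classifiers (linear-kernel soft-margin SVM, C ∈ {0.1, 1, 10}; L2 logistic
regression, C ∈ {0.01, 0.1, 1, 10}), and feature counts 1..min(15, p),
scored by stratified 5-fold cross-validated AUC with scaling and selection
refit inside every training fold. Ties resolve to fewer features, then
selector order, then classifier order. The winner is refit on the full
training split. The kernel and grids are declared choices — small-sample
stability and coefficient-based attribution motivated the linear kernel.
Train/test splitting is 7:3, stratified per endpoint, seeded.

AUCs use the Mann-Whitney statistic (ties half-weighted) with DeLong
structural-component variance; 95 % CIs are normal-approximation, clipped
to [0, 1]. Paired model comparisons use DeLong's test (two-sided).
Threshold metrics (Acc/Sen/Spe/PPV/NPV/MCC) come from one confusion matrix
at the Youden-optimal threshold frozen on training scores — freezing
avoids test-set leakage; MCC is 0 whenever a marginal is empty. Decision
curves report `NB(p_t) = TP/N − FP/N·p_t/(1−p_t)` against treat-all and
treat-none references; SVM scores are mapped to probabilities by a
logistic link fitted on training decision scores. Feature attribution for
the linear models is exact: `w_j·(z_ij − z̄_j)` reconstructs each score up
to the intercept; seeded permutation importance covers any non-linear
extension.

Cohort-characteristic comparisons use the Pearson chi-square
(`N(ad−bc)²/(r₁r₂c₁c₂)` on 2×2 collapses), switching to the Yates
continuity-corrected variant when any expected cell count is below 5 (the
conventional criterion; the comparison tables never state their rule), the
summary-statistic two-sample t-test (pooled or Welch), and the
Mann-Whitney U with tie-corrected normal approximation. Normality and
variance screening (Shapiro-Wilk, Levene) is delegated to standard
routines and not part of the contract.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: a 4096-voxel
phantom per noise condition, 50 seeds for cluster-number recovery (200
points per component), 100 effect-free cohorts of n = 200 and 10 planted
cohorts of n = 400 for calibration, and 500 replicates for the DeLong
type-I rate. K-means is scikit-learn's Lloyd implementation; the CH score,
DeLong components, ICC, Relief, GLCM, and both chi-square variants are
implemented directly from their defining formulas, with scikit-learn /
pingouin / scipy used as independent cross-checks in the tests, never as
the implementation under test.

## Known limitations

- The phantom's habitats are axis-aligned blocks with piecewise-constant
  parameters; real lesions have graded boundaries and correlated noise.
- At clinical SNR the CH criterion does not recover K = 4 from fitted
  voxel vectors of this phantom (see above); the cluster-number guarantee
  applies to the ≥ 4 SD separation regime.
- A single-voxel mask yields a degenerate mesh and an out-of-range
  sphericity; callers should treat sub-10-voxel regions as flagged.
- Decision-curve probabilities for SVMs depend on the training-fitted
  logistic link; no isotonic/Platt recalibration beyond that is applied.
- No Bayesian or simultaneous (unsegmented) IVIM fitting, no kurtosis
  term, no spatial regularization of habitat labels, and no D* in the
  clustering vector (D and f only).
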