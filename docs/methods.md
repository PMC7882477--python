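# Methods

## Model and procedure

The package locates condition-discriminative brain regions in two stages.

**Decoding stage.** Trials are vectors of in-mask voxel activations (one
acquired volume per trial in a sparse design; no GLM beta estimation is
performed — the raw volume is the feature vector). For every in-mask voxel a
searchlight — all in-mask voxels within a radius of the center — supplies the
feature subset for a binary linear classifier. The classifier is the
squared-hinge soft-margin linear SVM

  minimize ½ wᵀw + C Σᵢ max(1 − yᵢ wᵀxᵢ, 0)²,  yᵢ ∈ {+1, −1},

with an intercept that, as in liblinear's primal formulation, participates in
the regularizer. C is tuned per outer fold by an inner stratified k-fold grid
search maximizing the configured performance measure on pooled inner held-out
scores (ties resolved toward the smallest C, i.e. the strongest
regularization). The outer stratified k-fold loop gives every trial exactly
one held-out decision score; the pooled scores yield the searchlight
performance ρ_k: AUC (Mann–Whitney probability, ties credited ½ — identical
to trapezoidal ROC integration) or accuracy (sign agreement; a score of
exactly 0 predicts +1). ρ_k is mapped to the center voxel; the map may then
be smoothed with a mask-normalized Gaussian kernel.

**Inference stage.** The performance values over all K searchlights are
modeled as a two-component univariate Gaussian mixture — a dominant
non-informative component fluctuating around chance and an informative
component at higher performance — fitted by EM. The per-voxel posterior of
the non-informative component, p_SCIM, is thresholded: voxels with p_SCIM
below threshold **and** performance above chance (0.5) form the informative
region map. The above-chance gate exists because very low performance also
produces a low non-informative posterior without indicating information.
Benjamini–Hochberg FDR correction, when requested, is applied over the gated
candidate set (matching the observation that fewer above-chance voxels mean
fewer comparisons); whole-mask correction is available via `gate=False`.

Two reference procedures are implemented for comparison. The binomial test
evaluates the *point* probability C(N,n) p_Tⁿ p_F^(N−n) of n correct
classifications in N trials — this printed form, not the conventional
upper-tail sum, is what reproduces the boundary value ≈ 0.08 at n = 41,
N = 80; a `tail=True` variant provides the tail sum for users who want the
standard test. The permutation test reruns the entire searchlight
classification N_r times with globally shuffled labels (class counts
preserved; within-run shuffling is not implemented since no run structure is
modeled) and sets p = n_h/N_r with ties counting toward n_h and a floor at
1/N_r, the smallest attainable value. Group-level versions pool voxel-wise:
the mixture decomposition is applied to the across-subject mean map (by
default of the smoothed subject maps, since smoothing directly follows
classification in the single-subject pipeline); the group permutation null
draws one of each subject's r null maps per bootstrap sample and averages;
the group binomial sums per-subject correct counts over M·N trials. The
binomial test always operates on the raw held-out correct counts — a count
is only binomial before spatial averaging — so in the smoothed pipeline
variant smoothing enters the binomial result only through the above-chance
gate, which uses the smoothed performance map.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| searchlight radius | 3 (voxel units) | sphere radius; a mm metric is available for anisotropic voxels |
| map smoothing FWHM | 3 mm | Gaussian smoothing of the performance map (never of the raw data) |
| outer / inner CV folds | 10 / 5, stratified | nested cross-validation plan, derived deterministically from one seed shared by all searchlights |
| C grid | 10⁻³ … 10³, 7 log-spaced points | spans under- to over-regularized regimes |
| EM tolerance / max iterations | 1e-8 / 1000 | absolute log-likelihood increase stopping rule |
| EM restarts | 5 | first start deterministic, rest jittered from one seed |
| variance floor | 1e-6 | prevents component collapse; hitting it flags non-convergence |
| IRM threshold | 0.05 | cutoff on (adjusted) p_SCIM |
| permutation repetitions N_r | 100 | p-value resolution 1/N_r |
| group bootstrap n_boot | 100 000 | group-null resolution 1/n_boot |

EM initialization places μ_N at the sample median and μ_I at the 95th
percentile with priors (0.9, 0.1) and equal variances at the sample variance
— reflecting the premise that most of the brain is uninformative, which also
makes the dominant-component labeling stable. After fitting, components are
relabeled so μ_I ≥ μ_N, which resolves EM label switching. No lower bound is
imposed on π_I beyond the variance floor.

## Numerical choices

- The squared-hinge objective is strongly convex and piecewise quadratic; it
  is solved by a damped active-set Newton iteration (gradient tolerance
  1e-9) that terminates at the global optimum in a handful of steps. The
  solver is vectorized across searchlights — all searchlights of a dataset
  share the labels, fold plan and C grid, so whole batches (grouped by
  neighborhood size) are fitted with batched BLAS calls; a single-searchlight
  call is a batch of one, so batched and scalar paths produce identical
  numbers. Agreement with liblinear (scikit-learn `LinearSVC`) to ~1e-6 is
  enforced in the test suite.
- Posteriors are evaluated in log space (log-sum-exp), so simultaneous
  density underflow in both components cannot produce NaN.
- Map smoothing convolves value·mask and mask separately and divides, so
  values near the mask boundary are renormalized instead of shrinking toward
  the background; a constant map stays constant and σ_axis =
  FWHM / (2√(2 ln 2)) / voxel_size_axis.
- Searchlights are truncated at mask/grid boundaries (no padding); spheres
  smaller than 2 voxels are flagged but retained, since no exclusion rule is
  part of the procedure.
- Degenerate inputs raise: empty masks, single-class folds, non-finite
  activations, thresholds outside (0, 1], fewer than 10 values for the EM.

## The simulator, and what passing tests show

`simulate` emulates a sparse-imaging decoding experiment: 80 trials (40 per
condition), one volume each. Outside a template mask both conditions share
one voxel-wise normal distribution (defaults N(0, 1)); inside it activations
are class-specific (defaults: means ±Δ/2 with Δ = 0.5, unit SDs) and are
smoothed with a 3-mm-FWHM Gaussian confined to the template, giving the
local spatial correlation of real activations without leaking signal out.
The default grid is 30 × 30 × 20 voxels at 3 × 3 × 4 mm; the study-scale
tests use smaller grids (see below). The original moments came from real
recordings; here they are free parameters with the stated defaults.

The simulator does **not** model hemodynamic time courses, physiological or
scanner noise spectra, motion, inter-subject anatomical variability, or
non-Gaussian signal distributions. Passing tests therefore demonstrate the
statistical machinery — chance-level calibration, parameter recovery,
threshold robustness, specificity — under the stated generative model, not
performance on real fMRI data.

## Problem sizes in tests and scripts

End-to-end runs are scaled to desk size as the package's own test design:
the threshold-robustness study uses ten simulations on a 10 × 10 × 6 grid
with a radius-2 template blob, radius-2 searchlights and a reduced CV plan
(4 outer folds, 3 inner folds, C ∈ {10⁻², 1, 10²}); null-specificity runs
use 8 × 8 × 5 grids (6 × 6 × 4 with 25 permutations for the permutation
method); the accuracy-null experiment uses 200 *disjoint* 33-voxel
searchlights — the size of a radius-2 sphere — with the full default CV
plan, so the 200 null accuracies are independent draws (overlapping
searchlights share feature columns and would fluctuate together). The
reduced CV plan is used where many whole-volume maps are needed; fold counts
below the defaults raise map noise, which is why the study settings keep
3 inner folds rather than 2.

## Known limitations

- The mixture decomposition needs enough searchlights to resolve the
  histogram; K below a few hundred makes the informative component hard to
  identify, and data from a single component may be split arbitrarily
  (flagged by a near-zero π or near-zero d′).
- p_SCIM is a posterior under a fitted descriptive model, not a frequentist
  error rate; FDR control on p_SCIM values is heuristic.
- The d′-based global model selection variant (using map separation as a CV
  selection signal) is not implemented; model selection is inner-CV
  performance only.
- Permutation p-values inherit spatial correlation from overlapping
  searchlights; they are valid per voxel but not independent across voxels.
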