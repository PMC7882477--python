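# scim — searchlight classification informative region mixture model

`scim` identifies brain regions whose local multi-voxel BOLD patterns
discriminate two experimental conditions, and answers the question every
searchlight decoding study faces: *which voxels of the performance map are
actually informative?* It is aimed at fMRI researchers running MVPA
(multi-voxel pattern analysis) decoding experiments with two conditions and
one acquired volume per trial.

## The method

1. **Searchlight classification.** The masked volume is covered with
   overlapping near-spherical searchlights (default radius 3 voxels), one
   centered on every voxel. In each searchlight a soft-margin linear SVM,

   w\* = argmin_w ½ wᵀw + C Σᵢ max(1 − yᵢ wᵀxᵢ, 0)²,

   is trained and evaluated by nested cross-validation (the inner loop picks
   C by grid search, the outer loop scores held-out trials). Pooled held-out
   scores give the searchlight performance ρ_k — the AUC (probability that a
   random positive trial outscores a random negative one) or the accuracy —
   which is mapped to the center voxel and optionally smoothed (Gaussian,
   FWHM 3 mm).

2. **Mixture decomposition.** The map's value histogram is modeled as a
   two-component Gaussian mixture,

   P(ρ) = π_I N(ρ | μ_I, σ_I) + π_N N(ρ | μ_N, σ_N),

   fitted by EM: a dominant *non-informative* component fluctuating around
   chance, and an *informative* component at higher performance. The
   posterior probability that searchlight k is non-informative,

   p_SCIM(k) = π_N N(ρ_k|μ_N,σ_N) / [π_I N(ρ_k|μ_I,σ_I) + π_N N(ρ_k|μ_N,σ_N)],

   plays the role of a p-value: voxels with p_SCIM below threshold *and*
   performance above chance form the informative region map (IRM). Component
   separation is summarized by d′ = (μ_I − μ_N) / √(½(σ_I² + σ_N²)).

3. **Reference tests and group analysis.** For comparison the package
   implements the binomial test p_bin = C(N,n) p_Tⁿ p_F^(N−n), the random
   permutation test (p_rp = n_h/N_r, floored at 1/N_r), Benjamini–Hochberg
   FDR correction, and the group-level versions of all three (mean-map
   mixture decomposition, per-voxel bootstrap over per-subject null maps,
   and the pooled binomial over M·N trials).

A template-mask simulator generates fully synthetic datasets (80 trials, 40
per condition; class-specific activations inside a known template region,
label-independent noise outside) so the whole pipeline can be exercised and
scored against ground truth.

## Worked example

```python
import numpy as np
from scim import (CVConfig, SphereSpec, SimulationSpec, build_index,
                  fit_two_component_gmm, informative_region_map,
                  searchlight_map, simulate_trials, overlap)
from scim.simulate import build_template_mask
from scim.io import scatter_to_grid

shape = (10, 10, 6)
template = build_template_mask(shape, [((5, 5, 3), 2.0)])
spec = SimulationSpec(grid_shape=shape, template=template, seed=7)
trials, brain, template = simulate_trials(spec)

index = build_index(brain, SphereSpec(radius=2.0), spec.voxel_size)
cv = CVConfig(outer_folds=4, inner_folds=3, c_grid=[0.01, 1.0, 100.0], seed=0)
perf = searchlight_map(trials, index, cv).smooth(3.0, brain, spec.voxel_size)

fit = fit_two_component_gmm(perf.values, seed=0)
print(f"pi_N={fit.pi_N:.3f} mu_N={fit.mu_N:.3f} sigma_N={fit.sigma_N:.3f}")
print(f"pi_I={fit.pi_I:.3f} mu_I={fit.mu_I:.3f} sigma_I={fit.sigma_I:.3f}")
print(f"d_prime={fit.d_prime:.2f}")

irm = informative_region_map(perf, fit, threshold=0.05)
result = scatter_to_grid(irm.informative.astype(float), brain) > 0.5
print(f"informative voxels: {irm.informative.sum()}, "
      f"template overlap (Dice): {overlap(result, template).overlap:.2f}")
```

Output:

```
pi_N=0.615 mu_N=0.486 sigma_N=0.067
pi_I=0.385 mu_I=0.674 sigma_I=0.136
d_prime=1.75
informative voxels: 111, template overlap (Dice): 0.46
```

The non-informative component sits at chance (μ_N ≈ 0.49) and the
informative component at AUC ≈ 0.67, separated by d′ ≈ 1.8. The thresholded
IRM marks 111 of 600 voxels — more than the 33-voxel template, because any
searchlight whose sphere touches the template sees its signal (spatial
smearing inherent to searchlight mapping, further widened by map smoothing)
— giving a Dice overlap of 0.46 with the ground truth.

The same workflow is available from the shell:

```bash
scim simulate --seed 7 --grid 10 10 6 --out data/
scim classify --data data/ --radius 2 --outer-folds 4 --inner-folds 3 --out maps/
scim irm --map maps/performance_smoothed.nii --mask data/brain_mask.nii --out irm/
scim evaluate --result irm/irm.nii --template data/template_mask.nii --brain data/brain_mask.nii
```

(The default 30 × 30 × 20 grid with the full 10 × 5 × 7 nested-CV plan is a
multi-hour whole-volume run; the reduced settings above finish in about a
minute.)

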