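"""Group-level pooling for the three inference procedures.

All three pool voxel-wise across M subjects on a shared mask:

* SCIM: subject performance maps are averaged voxel-wise and the mixture
  decomposition plus thresholding is applied to the mean map exactly as in the
  single-subject analysis.
* Permutation: each subject contributes r null maps from label-shuffled reruns;
  a group null sample draws one of the r maps per subject (uniformly, with
  replacement across bootstrap samples) and averages across subjects; p is the
  fraction of n_boot null samples >= the observed group mean, floored at
  1/n_boot.
* Binomial: per-subject correct counts are summed voxel-wise and referred to
  the binomial point mass with M*N trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import PerformanceMap
from .mixture import (InformativeRegionMap, MixtureFit, fit_two_component_gmm,
                      informative_region_map)
from .stats import binomial_p_map

__all__ = ["GroupPermutationConfig", "group_scim_map", "group_mean_map",
           "group_permutation_map", "group_binomial_map"]


@dataclass
class GroupPermutationConfig:
    """r per-subject null maps, n_boot group-null bootstrap samples."""

    r: int = 100
    n_boot: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r < 1 or self.n_boot < 1:
            raise ValueError("r and n_boot must be >= 1")


def group_mean_map(perf_maps) -> PerformanceMap:
    """Voxel-wise mean of subject performance maps (shared mask and measure)."""
    perf_maps = list(perf_maps)
    if not perf_maps:
        raise ValueError("need at least one subject map")
    n = len(perf_maps[0].values)
    measure = perf_maps[0].measure
    for pm in perf_maps:
        if len(pm.values) != n:
            raise ValueError("subject maps differ in length (mask mismatch)")
        if pm.measure != measure:
            raise ValueError("subject maps mix performance measures")
    mean = np.mean([pm.values for pm in perf_maps], axis=0)
    return PerformanceMap(values=mean, measure=measure,
                          smoothed=any(pm.smoothed for pm in perf_maps))


def group_scim_map(perf_maps, threshold: float = 0.05, correction: str = "none",
                   em_seed: int = 0, **em_kwargs):
    """Mixture decomposition of the group mean map.

    Returns ``(irm, fit, mean_map)``; invariant to subject ordering.
    """
    mean_map = group_mean_map(perf_maps)
    fit = fit_two_component_gmm(mean_map.values, seed=em_seed, **em_kwargs)
    irm = informative_region_map(mean_map, fit, threshold=threshold,
                                 correction=correction)
    return irm, fit, mean_map


def group_permutation_map(mean_map: PerformanceMap, null_stacks,
                          config: GroupPermutationConfig) -> np.ndarray:
    """Bootstrap group-null p-value map from per-subject null stacks.

    ``null_stacks`` is (M, r, V): per subject, r label-shuffled performance
    maps over the V shared voxels. Per voxel, n_boot group-null means are
    formed by picking one of the r null values per subject; p = fraction of
    null means >= observed group mean (ties count), floored at 1/n_boot.
    """
    null = np.asarray(null_stacks, dtype=np.float64)
    if null.ndim != 3:
        raise ValueError("null_stacks must be (subjects, r, voxels)")
    M, r, V = null.shape
    if r != config.r:
        raise ValueError(f"expected r={config.r} null maps per subject, got {r}")
    if V != len(mean_map.values):
        raise ValueError("null stacks and mean map disagree on voxel count")
    rng = np.random.default_rng(config.seed)
    observed = mean_map.values
    counts = np.zeros(V, dtype=np.int64)
    # chunk the bootstrap to bound memory at ~chunk*M draws per voxel block
    chunk = max(1, min(config.n_boot, int(2e7 // max(M * V, 1)) or 1))
    done = 0
    while done < config.n_boot:
        b = min(chunk, config.n_boot - done)
        idx = rng.integers(0, r, size=(b, M, V))
        # gather null[m, idx[s, m, v], v] for each bootstrap sample s
        samp = null[np.arange(M)[None, :, None], idx, np.arange(V)[None, None, :]]
        means = samp.mean(axis=1)
        counts += (means >= observed[None, :]).sum(axis=0)
        done += b
    p = np.maximum(counts, 1) / config.n_boot
    return p


def group_binomial_map(n_correct_per_subject, N: int, p_T: float = 0.5,
                       tail: bool = False) -> np.ndarray:
    """Voxel-wise pooled binomial p from per-subject correct-count maps (M, V)."""
    counts = np.asarray(n_correct_per_subject, dtype=int)
    if counts.ndim != 2:
        raise ValueError("expected an (subjects, voxels) array of correct counts")
    if np.any((counts < 0) | (counts > N)):
        raise ValueError("per-subject counts must lie in [0, N]")
    M = counts.shape[0]
    return binomial_p_map(counts.sum(axis=0), N=M * N, p_T=p_T, tail=tail)
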