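"""Reference significance tests: binomial, random permutation, FDR.

The binomial test evaluates the point probability of exactly n correct
classifications in N trials,

    p_bin = C(N, n) * p_T^n * p_F^(N - n),   p_F = 1 - p_T,

which is the form used for map thresholding here; a conventional upper-tail
variant is available via ``tail=True``. The permutation test reruns the full
searchlight classification N_r times with globally shuffled labels and counts
null repetitions with performance >= observed; the resulting p is floored at
1/N_r, the smallest attainable value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .classify import CVConfig, PerformanceMap, searchlight_map
from .io import Mask, TrialSet
from .searchlight import SearchlightIndex

__all__ = ["BinomialSpec", "PermutationResult", "binomial_p", "group_binomial_p",
           "permutation_p_map", "fdr_bh"]


@dataclass
class BinomialSpec:
    """n correct classifications out of N trials, target-class prior p_T."""

    N: int
    n: int
    p_T: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.n <= self.N:
            raise ValueError(f"need 0 <= n <= N, got n={self.n}, N={self.N}")
        if not 0 < self.p_T < 1:
            raise ValueError(f"p_T must be in (0, 1), got {self.p_T}")

    @property
    def p_F(self) -> float:
        return 1.0 - self.p_T


@dataclass
class PermutationResult:
    """Permutation-test outcome for a whole map."""

    N_r: int
    n_h: np.ndarray          # per voxel: permutations with performance >= observed
    p_rp: np.ndarray         # floored at 1/N_r
    observed: PerformanceMap
    null_values: np.ndarray  # (N_r, n_voxels) null performance maps


def binomial_p(spec: BinomialSpec, tail: bool = False):
    """Binomial p-value for a correct-classification count.

    Default is the point-mass form C(N,n) p_T^n p_F^(N-n) (evaluated through
    the log-pmf for numerical safety); ``tail=True`` returns the upper-tail
    sum P(X >= n) instead.
    """
    if tail:
        return float(binom.sf(spec.n - 1, spec.N, spec.p_T))
    return float(np.exp(binom.logpmf(spec.n, spec.N, spec.p_T)))


def group_binomial_p(n_per_subject, N: int, p_T: float = 0.5, tail: bool = False) -> float:
    """Pooled binomial p: sum of per-subject correct counts out of M*N trials."""
    n_per_subject = np.asarray(n_per_subject, dtype=int)
    if n_per_subject.size < 1:
        raise ValueError("need at least one subject")
    if np.any(n_per_subject > N) or np.any(n_per_subject < 0):
        raise ValueError("each per-subject count must lie in [0, N]")
    M = n_per_subject.size
    return binomial_p(BinomialSpec(N=M * N, n=int(n_per_subject.sum()), p_T=p_T),
                      tail=tail)


def binomial_p_map(n_correct, N: int, p_T: float = 0.5, tail: bool = False) -> np.ndarray:
    """Vectorized per-voxel binomial p over a map of correct counts."""
    n_correct = np.asarray(n_correct, dtype=int)
    if tail:
        return binom.sf(n_correct - 1, N, p_T)
    return np.exp(binom.logpmf(n_correct, N, p_T))


def permutation_p_map(trials: TrialSet, index: SearchlightIndex, config: CVConfig,
                      N_r: int = 100, seed: int = 0,
                      smoothing_fwhm: float = 0.0, mask: Mask | None = None,
                      voxel_size=(1.0, 1.0, 1.0),
                      observed: PerformanceMap | None = None) -> PermutationResult:
    """Random permutation test over all searchlights.

    Each of the N_r repetitions globally shuffles the label sequence (class
    counts preserved) with a repetition-specific seed derived from ``seed`` and
    reruns the full searchlight classification. Ties count toward n_h
    ("equal or higher"); p_rp = n_h / N_r floored at 1/N_r. If a smoothing
    FWHM is given, observed and null maps are smoothed identically before
    comparison. The null maps are retained for group-level reuse.
    """
    if N_r < 1:
        raise ValueError(f"N_r must be >= 1, got {N_r}")
    if smoothing_fwhm > 0 and mask is None:
        raise ValueError("smoothing requires the mask")

    def _finalize(pm: PerformanceMap) -> PerformanceMap:
        return pm.smooth(smoothing_fwhm, mask, voxel_size) if smoothing_fwhm > 0 else pm

    if observed is None:
        observed = searchlight_map(trials, index, config)
    observed = _finalize(observed)
    rng = np.random.default_rng(seed)
    null_values = np.empty((N_r, index.k_total))
    for rep in range(N_r):
        perm = rng.permutation(trials.n_trials)
        shuffled = TrialSet(activations=trials.activations,
                            labels=trials.labels[perm], run_id=trials.run_id)
        null_values[rep] = _finalize(searchlight_map(shuffled, index, config)).values
    n_h = (null_values >= observed.values[None, :]).sum(axis=0)
    p_rp = np.maximum(n_h, 1) / N_r
    return PermutationResult(N_r=N_r, n_h=n_h, p_rp=p_rp, observed=observed,
                             null_values=null_values)


def fdr_bh(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up: returns (adjusted p-values, pass mask)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q
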