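"""Ground-truth evaluation of result maps against the simulation template.

Overlap uses the symmetric ratio n_(t&r) / (0.5 * (n_t + n_r)) — identical to
the Dice coefficient. Sensitivity/specificity treat template voxels as the
positive class within the brain mask; sweeping the significance threshold
yields one ROC point per threshold. Threshold sweeps also report the average
inverse slope of the informative-fraction curve over a p interval (default
0.01-0.05): small absolute inverse slope change means the method is robust to
the exact threshold choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OverlapResult", "ThresholdSweep", "overlap", "detection_rates",
           "threshold_sweep"]


@dataclass
class OverlapResult:
    n_intersection: int
    n_template: int
    n_result: int
    overlap: float


@dataclass
class ThresholdSweep:
    thresholds: np.ndarray
    fraction: np.ndarray        # informative fraction of all searchlights
    inverse_slope: float
    interval: tuple[float, float]


def _as_bool(x) -> np.ndarray:
    members = getattr(x, "members", x)
    return np.asarray(members, dtype=bool)


def overlap(result, template) -> OverlapResult:
    """Symmetric template/result overlap (Dice); 0 when both maps are empty."""
    r, t = _as_bool(result), _as_bool(template)
    if r.shape != t.shape:
        raise ValueError(f"shape mismatch: result {r.shape} vs template {t.shape}")
    n_r, n_t = int(r.sum()), int(t.sum())
    n_i = int((r & t).sum())
    denom = 0.5 * (n_t + n_r)
    return OverlapResult(n_intersection=n_i, n_template=n_t, n_result=n_r,
                         overlap=0.0 if denom == 0 else n_i / denom)


def detection_rates(result, template, brain):
    """(sensitivity, specificity) of a binary result map within the brain mask."""
    r, t, b = _as_bool(result), _as_bool(template), _as_bool(brain)
    if not (r.shape == t.shape == b.shape):
        raise ValueError("result, template and brain masks must share a shape")
    if np.any(t & ~b) or np.any(r & ~b):
        raise ValueError("template and result must lie within the brain mask")
    n_t = int(t.sum())
    if n_t == 0:
        raise ValueError("sensitivity is undefined for an empty template")
    negatives = b & ~t
    if not negatives.any():
        raise ValueError("specificity is undefined: template covers the "
                         "entire brain mask")
    sensitivity = int((r & t).sum()) / n_t
    specificity = int((negatives & ~r).sum()) / int(negatives.sum())
    return sensitivity, specificity


def threshold_sweep(pvalues, perf_values, thresholds,
                    interval=(0.01, 0.05), chance: float = 0.5) -> ThresholdSweep:
    """Informative fraction vs p threshold, with the above-chance gate applied.

    ``inverse_slope`` is the net threshold change divided by the net fraction
    change over ``interval`` (np.inf when the curve is flat there — maximal
    robustness).
    """
    p = np.asarray(pvalues, dtype=np.float64)
    perf = np.asarray(perf_values, dtype=np.float64)
    thr = np.sort(np.asarray(thresholds, dtype=np.float64))
    if thr.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any((thr <= 0) | (thr > 1)):
        raise ValueError("thresholds must lie in (0, 1]")
    candidates = perf > chance
    fraction = np.array([(candidates & (p < t)).mean() for t in thr])
    lo, hi = min(interval), max(interval)
    f_lo = (candidates & (p < lo)).mean()
    f_hi = (candidates & (p < hi)).mean()
    df = f_hi - f_lo
    inverse_slope = np.inf if df == 0 else (hi - lo) / df
    return ThresholdSweep(thresholds=thr, fraction=fraction,
                          inverse_slope=float(inverse_slope), interval=(lo, hi))
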