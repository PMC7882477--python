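"""End-to-end workflows: single-subject analysis and the simulation study.

The single-subject pipeline is: searchlight classification -> (optional)
spatial smoothing of the performance map -> inference (mixture decomposition,
permutation test, or binomial test) -> thresholded informative region map.
The simulation study repeats simulate -> analyze -> score-against-template
over fresh seeds and tabulates overlap/sensitivity/specificity per method,
smoothing variant, correction, and threshold.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .classify import CVConfig, PerformanceMap, searchlight_map
from .evaluate import detection_rates, overlap
from .io import Mask, TrialSet, scatter_to_grid
from .mixture import fit_two_component_gmm, informative_region_map
from .searchlight import SphereSpec, build_index
from .simulate import SimulationSpec, simulate_trials
from .stats import binomial_p_map, fdr_bh, permutation_p_map

__all__ = ["threshold_pmap", "run_single_subject", "run_simulation_study"]

METHODS = ("scim", "perm", "binom")


def threshold_pmap(p, perf_values, threshold: float = 0.05,
                   correction: str = "none", chance: float = 0.5):
    """Binary informative map from a p-value map plus the above-chance gate.

    Used for the reference tests; mirrors the IRM rule (FDR, when requested,
    is applied over the gated candidate set).
    """
    p = np.asarray(p, dtype=np.float64)
    perf = np.asarray(perf_values, dtype=np.float64)
    candidates = perf > chance
    if correction == "fdr":
        p_eff = np.ones_like(p)
        if candidates.any():
            adj, _ = fdr_bh(p[candidates], q=threshold)
            p_eff[candidates] = adj
    elif correction == "none":
        p_eff = p
    else:
        raise ValueError(f"correction must be 'none' or 'fdr', got {correction!r}")
    return candidates & (p_eff < threshold)


def run_single_subject(trials: TrialSet, brain: Mask, *, voxel_size=(1.0, 1.0, 1.0),
                       sphere: SphereSpec | None = None, cv: CVConfig | None = None,
                       fwhm: float = 3.0, method: str = "scim",
                       threshold: float = 0.05, correction: str = "none",
                       n_perm: int = 100, em_seed: int = 0,
                       perm_seed: int = 0) -> dict:
    """Full single-subject analysis; returns a dict of all stage artifacts.

    Keys: ``perf`` (raw map), ``perf_final`` (after smoothing), ``informative``
    (binary map over the mask linearization), ``p`` (p_SCIM or test p-values),
    and method-specific extras (``fit`` for scim, ``perm`` result, counts for
    binom). Deterministic given (inputs, settings, seeds).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    sphere = sphere or SphereSpec(radius=3.0)
    cv = cv or CVConfig()
    index = build_index(brain, sphere, voxel_size)
    perf = searchlight_map(trials, index, cv)
    perf_final = perf.smooth(fwhm, brain, voxel_size) if fwhm > 0 else perf
    out = {"index": index, "perf": perf, "perf_final": perf_final,
           "method": method, "threshold": threshold, "correction": correction}
    if method == "scim":
        fit = fit_two_component_gmm(perf_final.values, seed=em_seed)
        irm = informative_region_map(perf_final, fit, threshold=threshold,
                                     correction=correction)
        out.update(fit=fit, irm=irm, p=irm.p_scim, informative=irm.informative)
    elif method == "perm":
        res = permutation_p_map(trials, index, cv, N_r=n_perm, seed=perm_seed,
                                smoothing_fwhm=fwhm, mask=brain,
                                voxel_size=voxel_size, observed=perf)
        out.update(perm=res, p=res.p_rp,
                   informative=threshold_pmap(res.p_rp, perf_final.values,
                                              threshold, correction))
    else:  # binom
        p = binomial_p_map(perf.n_correct, N=trials.n_trials)
        out.update(p=p, n_correct=perf.n_correct,
                   informative=threshold_pmap(p, perf_final.values,
                                              threshold, correction))
    return out


def _analyze_one(trials, brain, template, voxel_size, sphere, cv, fwhm_values,
                 thresholds, n_perm, seed):
    """All three methods on one dataset, for each smoothing variant."""
    index = build_index(brain, sphere, voxel_size)
    perf = searchlight_map(trials, index, cv)
    rows = []
    for fwhm in fwhm_values:
        perf_v = perf.smooth(fwhm, brain, voxel_size) if fwhm > 0 else perf
        pmaps = {}
        fit = fit_two_component_gmm(perf_v.values, seed=seed)
        pmaps["scim"] = informative_region_map(perf_v, fit, threshold=1.0).p_scim
        pmaps["binom"] = binomial_p_map(perf.n_correct, N=trials.n_trials)
        if n_perm > 0:
            res = permutation_p_map(trials, index, cv, N_r=n_perm, seed=seed,
                                    smoothing_fwhm=fwhm, mask=brain,
                                    voxel_size=voxel_size, observed=perf)
            pmaps["perm"] = res.p_rp
        for method, p in pmaps.items():
            for correction in ("none", "fdr"):
                for thr in thresholds:
                    inf = threshold_pmap(p, perf_v.values, thr, correction)
                    inf_grid = scatter_to_grid(inf.astype(float), brain) > 0.5
                    ov = overlap(inf_grid, template.members)
                    sens, spec = detection_rates(inf_grid, template.members,
                                                 brain.members)
                    rows.append(dict(method=method, smoothed=fwhm > 0,
                                     correction=correction, threshold=thr,
                                     overlap=ov.overlap, sensitivity=sens,
                                     specificity=spec,
                                     n_informative=int(inf.sum())))
    return rows


def run_simulation_study(n_repetitions: int = 10, sim_spec: SimulationSpec | None = None,
                         sphere: SphereSpec | None = None, cv: CVConfig | None = None,
                         thresholds=(0.001, 0.01, 0.05, 0.1, 0.5),
                         fwhm_values=(0.0, 3.0), n_perm: int = 100,
                         seed: int = 0) -> pd.DataFrame:
    """Repeated simulate-and-analyze study over all three methods.

    Each repetition draws a fresh dataset (seed derived from ``seed``), runs
    searchlight classification once, then evaluates SCIM, the binomial test
    and (if ``n_perm > 0``) the permutation test for every smoothing variant,
    correction, and threshold against the known template. Returns a tidy
    DataFrame with one row per (repetition, method, smoothed, correction,
    threshold) cell; aggregate with ``groupby(...).median()`` / quantiles for
    the study summary.
    """
    sim_spec = sim_spec or SimulationSpec()
    sphere = sphere or SphereSpec(radius=3.0)
    cv = cv or CVConfig()
    all_rows = []
    for rep in range(n_repetitions):
        rep_seed = seed + 1000 * rep
        spec = replace(sim_spec, seed=rep_seed)
        trials, brain, template = simulate_trials(spec)
        rows = _analyze_one(trials, brain, template, spec.voxel_size, sphere,
                            replace(cv, seed=rep_seed), fwhm_values, thresholds,
                            n_perm, rep_seed)
        for r in rows:
            r["rep"] = rep
        all_rows.extend(rows)
    return pd.DataFrame(all_rows)


def summarize_study(table: pd.DataFrame) -> pd.DataFrame:
    """Median and inter-quartile range across repetitions per analysis cell."""
    keys = ["method", "smoothed", "correction", "threshold"]
    g = table.groupby(keys)[["overlap", "sensitivity", "specificity"]]
    med = g.median().add_suffix("_median")
    iqr = (g.quantile(0.75) - g.quantile(0.25)).add_suffix("_iqr")
    return med.join(iqr).reset_index()
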