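"""Two-component Gaussian mixture decomposition of searchlight performance maps.

The distribution of per-searchlight performance values rho_k over the brain is
modelled as

    P(rho) = pi_I * N(rho | mu_I, sigma_I) + pi_N * N(rho | mu_N, sigma_N),

where the N component collects non-informative searchlights fluctuating around
chance and the I component the informative ones (mu_I >= mu_N by labeling
convention). Parameters are estimated by expectation-maximization on the whole
map. The posterior probability that searchlight k is non-informative,

    p_SCIM(k) = pi_N N(rho_k|mu_N,sigma_N) / [pi_I N(rho_k|mu_I,sigma_I)
                                              + pi_N N(rho_k|mu_N,sigma_N)],

plays the role of a p-value: voxels with p_SCIM below threshold (and
performance above chance) constitute the informative region map (IRM).
Component separation is summarized by the sensitivity index

    d' = (mu_I - mu_N) / sqrt((sigma_I^2 + sigma_N^2) / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .classify import PerformanceMap

__all__ = ["MixtureFit", "InformativeRegionMap", "TwoComponentGaussianMixture",
           "fit_two_component_gmm", "posterior_noninformative",
           "posterior_informative", "d_prime", "informative_region_map"]

_MIN_VALUES = 10


@dataclass
class MixtureFit:
    """The six mixture parameters plus fit diagnostics."""

    pi_I: float
    pi_N: float
    mu_I: float
    mu_N: float
    sigma_I: float
    sigma_N: float
    log_likelihood: float
    n_iter: int
    converged: bool
    d_prime: float
    ll_trace: np.ndarray | None = None


@dataclass
class InformativeRegionMap:
    """Per-voxel non-informativeness posterior and the thresholded binary map."""

    p_scim: np.ndarray
    informative: np.ndarray
    threshold: float
    corrected: str = "none"
    p_adjusted: np.ndarray | None = None


def d_prime(mu_I: float, mu_N: float, sigma_I: float, sigma_N: float) -> float:
    """Sensitivity index of two normal components (pooled-SD units)."""
    if sigma_I <= 0 or sigma_N <= 0:
        raise ValueError("standard deviations must be positive")
    return (mu_I - mu_N) / np.sqrt(0.5 * (sigma_I ** 2 + sigma_N ** 2))


class TwoComponentGaussianMixture(BaseEstimator):
    """EM fit of the univariate two-component normal mixture.

    Component 0 is non-informative (lower mean), component 1 informative;
    labels are assigned by mean order after fitting, which resolves EM label
    switching. Initialization places mu_N at the sample median and mu_I at the
    95th percentile with priors (0.9, 0.1), reflecting the premise that most of
    the brain is uninformative; ``n_restarts - 1`` additional runs start from
    seeded jitters of this point and the best final likelihood wins.

    Parameters
    ----------
    tol : float
        EM stops when the absolute log-likelihood increase falls below this.
    max_iter : int
        Iteration cap per restart.
    n_restarts : int
        Number of EM runs (first deterministic, rest jittered).
    seed : int
        Seed for the jittered restarts.
    var_floor : float
        Lower bound on component variances; hitting it flags non-convergence.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 1000,
                 n_restarts: int = 5, seed: int = 0, var_floor: float = 1e-6):
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.seed = seed
        self.var_floor = var_floor

    # --- EM internals -----------------------------------------------------

    @staticmethod
    def _log_joint(x, pi, mu, sigma):
        """log(pi_c) + log N(x | mu_c, sigma_c) for both components; (n, 2)."""
        return (np.log(pi)[None, :]
                + norm.logpdf(x[:, None], loc=mu[None, :], scale=sigma[None, :]))

    def _run_em(self, x, pi, mu, var):
        floor_hit = False
        trace = []
        ll_prev = -np.inf
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            lj = self._log_joint(x, pi, mu, np.sqrt(var))
            ll_n = logsumexp(lj, axis=1)
            ll = float(ll_n.sum())
            trace.append(ll)
            resp = np.exp(lj - ll_n[:, None])  # E-step responsibilities
            if ll - ll_prev < self.tol and n_iter > 1:
                converged = True
                break
            ll_prev = ll
            # M-step
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-300)
            pi = nk / len(x)
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            if np.any(var < self.var_floor):
                floor_hit = True
                var = np.maximum(var, self.var_floor)
        return pi, mu, var, trace, n_iter, converged and not floor_hit

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=np.float64).ravel()
        if x.size < _MIN_VALUES:
            raise ValueError(f"need at least {_MIN_VALUES} values, got {x.size}")
        if not np.all(np.isfinite(x)):
            raise ValueError("values contain non-finite entries")
        s = max(float(np.var(x)), self.var_floor)
        base_mu = np.array([np.median(x), np.percentile(x, 95.0)])
        base_pi = np.array([0.9, 0.1])
        rng = np.random.default_rng(self.seed)
        best = None
        for r in range(self.n_restarts):
            if r == 0:
                mu0, pi0, var0 = base_mu.copy(), base_pi.copy(), np.array([s, s])
            else:
                mu0 = base_mu + rng.normal(0, np.sqrt(s) * 0.5, size=2)
                p = float(np.clip(0.9 + rng.normal(0, 0.05), 0.5, 0.99))
                pi0 = np.array([p, 1 - p])
                var0 = s * rng.uniform(0.5, 1.5, size=2)
            out = self._run_em(x, pi0, mu0, np.maximum(var0, self.var_floor))
            if best is None or out[3][-1] > best[3][-1]:
                best = out
        pi, mu, var, trace, n_iter, converged = best
        order = np.argsort(mu)  # component 0 = non-informative (lower mean)
        pi, mu, var = pi[order], mu[order], var[order]
        self.weights_ = pi
        self.means_ = mu
        self.sigmas_ = np.sqrt(var)
        self.log_likelihood_ = trace[-1]
        self.ll_trace_ = np.asarray(trace)
        self.n_iter_ = n_iter
        self.converged_ = bool(converged)
        self.d_prime_ = d_prime(mu[1], mu[0], self.sigmas_[1], self.sigmas_[0])
        return self

    def predict_proba(self, X):
        """Posterior [non-informative, informative] per value (log-space safe)."""
        x = np.asarray(X, dtype=np.float64).ravel()
        lj = self._log_joint(x, self.weights_, self.means_, self.sigmas_)
        return np.exp(lj - logsumexp(lj, axis=1)[:, None])

    def score(self, X, y=None):
        x = np.asarray(X, dtype=np.float64).ravel()
        lj = self._log_joint(x, self.weights_, self.means_, self.sigmas_)
        return float(np.mean(logsumexp(lj, axis=1)))

    def to_fit(self) -> MixtureFit:
        return MixtureFit(
            pi_I=float(self.weights_[1]), pi_N=float(self.weights_[0]),
            mu_I=float(self.means_[1]), mu_N=float(self.means_[0]),
            sigma_I=float(self.sigmas_[1]), sigma_N=float(self.sigmas_[0]),
            log_likelihood=float(self.log_likelihood_), n_iter=int(self.n_iter_),
            converged=bool(self.converged_), d_prime=float(self.d_prime_),
            ll_trace=self.ll_trace_)


def fit_two_component_gmm(values, tol: float = 1e-8, max_iter: int = 1000,
                          n_restarts: int = 5, seed: int = 0,
                          var_floor: float = 1e-6) -> MixtureFit:
    """EM fit of the two-component mixture; see :class:`TwoComponentGaussianMixture`."""
    est = TwoComponentGaussianMixture(tol=tol, max_iter=max_iter,
                                      n_restarts=n_restarts, seed=seed,
                                      var_floor=var_floor)
    return est.fit(values).to_fit()


def _log_components(rho, fit: MixtureFit):
    rho = np.asarray(rho, dtype=np.float64)
    log_n = np.log(fit.pi_N) + norm.logpdf(rho, fit.mu_N, fit.sigma_N)
    log_i = np.log(fit.pi_I) + norm.logpdf(rho, fit.mu_I, fit.sigma_I)
    return log_n, log_i


def posterior_noninformative(rho, fit: MixtureFit):
    """p_SCIM: posterior probability of the non-informative component at rho.

    Evaluated in log-space so that simultaneous density underflow cannot
    produce NaN.
    """
    log_n, log_i = _log_components(rho, fit)
    denom = np.logaddexp(log_n, log_i)
    out = np.exp(log_n - denom)
    if np.ndim(rho) == 0:
        return float(out)
    return out


def posterior_informative(rho, fit: MixtureFit):
    """Complement of :func:`posterior_noninformative`."""
    log_n, log_i = _log_components(rho, fit)
    denom = np.logaddexp(log_n, log_i)
    out = np.exp(log_i - denom)
    if np.ndim(rho) == 0:
        return float(out)
    return out


def informative_region_map(perf: PerformanceMap, fit: MixtureFit,
                           threshold: float = 0.05, correction: str = "none",
                           q: float | None = None, chance: float = 0.5,
                           gate: bool = True) -> InformativeRegionMap:
    """Threshold the p_SCIM map into the informative region map.

    Only voxels with performance above chance are candidates (low performance
    also yields low non-informativeness posterior but is not informative).
    With ``correction="fdr"`` Benjamini-Hochberg adjusted p-values over the
    candidate set are compared to the threshold (``q`` defaults to it); with
    ``gate=False`` the candidate set is the whole mask.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if correction not in ("none", "fdr"):
        raise ValueError(f"correction must be 'none' or 'fdr', got {correction!r}")
    cutoff = threshold if q is None else q
    p_scim = posterior_noninformative(perf.values, fit)
    candidates = perf.values > chance if gate else np.ones_like(p_scim, bool)
    p_adjusted = None
    if correction == "fdr":
        p_eff = np.ones_like(p_scim)
        if candidates.any():
            _, adj, _, _ = multipletests(p_scim[candidates], alpha=cutoff,
                                         method="fdr_bh")
            p_eff[candidates] = adj
        p_adjusted = p_eff
    else:
        p_eff = p_scim
    informative = candidates & (p_eff < cutoff)
    return InformativeRegionMap(p_scim=p_scim, informative=informative,
                                threshold=cutoff, corrected=correction,
                                p_adjusted=p_adjusted)
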