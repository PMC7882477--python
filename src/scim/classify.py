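"""Per-searchlight soft-margin linear SVM with nested cross-validation.

For each searchlight the trials' in-sphere voxel vectors are classified with a
linear SVM minimizing

    (1/2) w'w + C * sum_i max(1 - y_i w'x_i, 0)^2

(squared hinge loss; an intercept is included and, like liblinear, enters the
regularizer). The regularization constant C is chosen per outer fold by an
inner grid-search cross-validation, and the outer loop assigns every trial
exactly one held-out decision score. Pooled held-out scores yield the
searchlight's performance rho_k, either the area under the ROC curve
(probability that a random positive trial outscores a random negative one,
ties counted half) or the fraction of correctly signed predictions. rho_k is
mapped to the searchlight's center voxel, giving the information-based map.

The objective is piecewise quadratic and strongly convex, so it is solved
exactly by a damped active-set Newton iteration. Because every searchlight of
a dataset shares the labels, the fold plan and the C grid, the solver runs
batched over searchlights (grouped by feature count); a per-searchlight call
is just a batch of one, so batched and scalar paths coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold, StratifiedKFold

from .io import Mask, TrialSet
from .searchlight import SearchlightIndex, smooth_map

__all__ = ["SVMModel", "CVConfig", "PerformanceMap", "train_linear_svm",
           "decision_scores", "score_performance", "cv_scores",
           "searchlight_map", "SearchlightDecoder"]

#: cap on searchlights fitted in one batch (memory bound)
_BATCH = 1024


@dataclass
class SVMModel:
    """Fitted linear SVM: weight vector w*, intercept, and the C used."""

    weights: np.ndarray
    bias: float
    C: float


def _default_c_grid() -> np.ndarray:
    return np.logspace(-3, 3, 7)


@dataclass
class CVConfig:
    """Nested cross-validation settings.

    outer_folds / inner_folds default to 10 / 5 stratified folds; c_grid is
    log-spaced over 1e-3..1e3. The fold plan is a deterministic function of
    ``seed`` and the label sequence only, so all searchlights of one dataset
    share a common plan and maps are comparable voxel to voxel.
    """

    outer_folds: int = 10
    inner_folds: int = 5
    c_grid: np.ndarray = field(default_factory=_default_c_grid)
    seed: int = 0
    measure: str = "auc"  # "auc" or "accuracy"
    stratified: bool = True

    def __post_init__(self) -> None:
        self.c_grid = np.atleast_1d(np.asarray(self.c_grid, dtype=float))
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.c_grid.size == 0 or np.any(self.c_grid <= 0):
            raise ValueError("c_grid must be non-empty and positive")
        if self.measure not in ("auc", "accuracy"):
            raise ValueError(f"measure must be 'auc' or 'accuracy', got {self.measure!r}")


@dataclass
class PerformanceMap:
    """Per-searchlight performance rho_k over the mask linearization."""

    values: np.ndarray
    measure: str
    smoothed: bool = False
    k_total: int = 0
    n_correct: np.ndarray | None = None  # held-out correct counts (for binomial tests)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.k_total == 0:
            self.k_total = len(self.values)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("performance values must lie in [0, 1]")

    def smooth(self, fwhm_mm: float, mask: Mask, voxel_size=(1.0, 1.0, 1.0)) -> "PerformanceMap":
        values = smooth_map(self.values, fwhm_mm, mask, voxel_size)
        return PerformanceMap(values=values, measure=self.measure,
                              smoothed=fwhm_mm > 0, k_total=self.k_total,
                              n_correct=self.n_correct)


# --- squared-hinge solver -------------------------------------------------

def _fit_sqhinge_batch(X3: np.ndarray, y: np.ndarray, C: float,
                       tol: float = 1e-9, max_iter: int = 100) -> np.ndarray:
    """Exact batched minimizer of the squared-hinge objective.

    X3 is (K, n, d); returns augmented weights (K, d+1) with the intercept in
    the last coordinate. Damped Newton on the active set: the objective is
    strongly convex (Hessian >= I) and piecewise quadratic, so the iteration
    terminates at the global optimum after a handful of steps.
    """
    K, n, d = X3.shape
    Xy = np.concatenate([X3, np.ones((K, n, 1))], axis=2) * y[None, :, None]
    D = d + 1
    W = np.zeros((K, D))
    eye = np.eye(D)[None]

    def objective(Wc):
        margins = 1.0 - np.einsum("knd,kd->kn", Xy, Wc)
        return 0.5 * np.einsum("kd,kd->k", Wc, Wc) + C * np.sum(
            np.maximum(margins, 0.0) ** 2, axis=1)

    f = objective(W)
    done = np.zeros(K, dtype=bool)
    for _ in range(max_iter):
        margins = 1.0 - np.einsum("knd,kd->kn", Xy, W)
        act = np.maximum(margins, 0.0)
        grad = W - 2.0 * C * np.einsum("knd,kn->kd", Xy, act)
        gmax = np.abs(grad).max(axis=1)
        done |= gmax <= tol * (1.0 + np.abs(W).max(axis=1))
        if done.all():
            break
        XyA = Xy * (margins > 0)[:, :, None]
        H = eye + 2.0 * C * np.matmul(XyA.transpose(0, 2, 1), Xy)
        step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        t = np.ones(K)
        W_new, f_new = W - step, None
        for _ in range(40):  # backtracking, vectorized over the batch
            W_new = W - t[:, None] * step
            f_new = objective(W_new)
            bad = ~done & (f_new > f + 1e-12 * (1.0 + np.abs(f)))
            if not bad.any():
                break
            t[bad] *= 0.5
        upd = ~done
        W[upd] = W_new[upd]
        f[upd] = f_new[upd]
    return W


def train_linear_svm(features: np.ndarray, labels: np.ndarray, C: float,
                     tol: float = 1e-9, max_iter: int = 100) -> SVMModel:
    """Fit the squared-hinge soft-margin linear SVM at a fixed C.

    Deterministic; solves the strongly convex objective to tolerance ``tol``
    on the gradient. Matches liblinear's primal formulation (intercept
    regularized) to solver precision.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain non-finite values")
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    W = _fit_sqhinge_batch(features[None], labels, C, tol=tol, max_iter=max_iter)[0]
    return SVMModel(weights=W[:-1].copy(), bias=float(W[-1]), C=C)


def decision_scores(model: SVMModel, features: np.ndarray) -> np.ndarray:
    """Signed distance proxy w'x + b; positive predicts label +1."""
    return np.asarray(features, dtype=np.float64) @ model.weights + model.bias


# --- performance measures -------------------------------------------------

def _auc_batch(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC per row of ``scores`` (K, n); ties credited 1/2."""
    pos = labels > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores, axis=-1)
    r_pos = ranks[..., pos].sum(axis=-1)
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def score_performance(scores: np.ndarray, labels: np.ndarray, measure: str = "auc") -> float:
    """Pool held-out scores into one performance value in [0, 1].

    "auc": probability that a random positive trial outscores a random
    negative one, ties counted 1/2 (identical to trapezoidal ROC
    integration). "accuracy": fraction of trials whose score sign matches the
    label (score 0 predicts +1), resolution 1/n.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("performance is undefined with a single class")
    if measure == "auc":
        return float(_auc_batch(scores[None], labels)[0])
    if measure == "accuracy":
        pred = np.where(scores >= 0, 1, -1)
        return float(np.mean(pred == labels))
    raise ValueError(f"unknown measure {measure!r}")


def _measure_batch(scores: np.ndarray, labels: np.ndarray, measure: str) -> np.ndarray:
    if measure == "auc":
        return _auc_batch(scores, labels)
    pred = np.where(scores >= 0, 1, -1)
    return np.mean(pred == labels[None, :], axis=1)


# --- nested cross-validation ----------------------------------------------

def _fold_maker(n_splits: int, stratified: bool, seed: int):
    cls = StratifiedKFold if stratified else KFold
    return cls(n_splits=n_splits, shuffle=True, random_state=seed)


def _cv_scores_batch(X3: np.ndarray, y: np.ndarray, config: CVConfig) -> np.ndarray:
    """Held-out decision scores (K, n) for a batch of same-width searchlights."""
    K, n, _ = X3.shape
    scores = np.empty((K, n))
    outer = _fold_maker(config.outer_folds, config.stratified, config.seed)
    for tr, te in outer.split(X3[0], y):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("an outer training fold lost one class; "
                             "reduce outer_folds or enable stratification")
        X_tr, y_tr = X3[:, tr], y[tr]
        # inner grid search: per searchlight, best C by pooled inner held-out measure
        best_perf = np.full(K, -np.inf)
        best_idx = np.zeros(K, dtype=int)
        inner = list(_fold_maker(config.inner_folds, config.stratified,
                                 config.seed + 1).split(X_tr[0], y_tr))
        for ci, C in enumerate(config.c_grid):
            inner_scores = np.empty((K, len(tr)))
            for itr, ite in inner:
                W = _fit_sqhinge_batch(X_tr[:, itr], y_tr[itr].astype(float), C)
                inner_scores[:, ite] = (
                    np.einsum("knd,kd->kn", X_tr[:, ite], W[:, :-1]) + W[:, -1:])
            perf = _measure_batch(inner_scores, y_tr, config.measure)
            better = perf > best_perf + 1e-12  # ties keep the smaller C
            best_perf[better] = perf[better]
            best_idx[better] = ci
        # final outer-fold fit, grouped by the chosen C
        for ci in np.unique(best_idx):
            sel = best_idx == ci
            W = _fit_sqhinge_batch(X_tr[sel], y_tr.astype(float), config.c_grid[ci])
            scores[np.ix_(sel, te)] = (
                np.einsum("knd,kd->kn", X3[np.ix_(sel, te)], W[:, :-1])
                + W[:, -1:])
    return scores


def cv_scores(features: np.ndarray, labels: np.ndarray, config: CVConfig):
    """Nested-CV held-out decision scores and predictions for one searchlight.

    Returns ``(scores, predicted)`` where each trial's entries come from the
    single outer fold in which it was held out. The fold plan depends only on
    ``(labels, config.seed)``.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    scores = _cv_scores_batch(X[None], y, config)[0]
    predicted = np.where(scores >= 0, 1, -1)
    return scores, predicted


def searchlight_map(trials: TrialSet, index: SearchlightIndex,
                    config: CVConfig) -> PerformanceMap:
    """Run the nested-CV classifier in every searchlight.

    rho_k (the configured measure) is assigned to each center voxel;
    searchlights are statistically independent, so processing order cannot
    change the map (they are batched by neighborhood size purely for speed).
    The per-searchlight held-out correct-prediction counts are kept on the map
    (``n_correct``) for use by count-based significance tests.
    """
    y = trials.labels
    values = np.empty(index.k_total)
    n_correct = np.empty(index.k_total, dtype=int)
    sizes = index.sizes()
    feats = trials.activations.T  # (V, n): row gather per neighborhood
    for d in np.unique(sizes):
        ks = np.flatnonzero(sizes == d)
        for start in range(0, len(ks), _BATCH):
            kchunk = ks[start:start + _BATCH]
            cols = np.stack([index.neighborhoods[k] for k in kchunk])
            X3 = feats[cols].transpose(0, 2, 1)  # (K, n, d)
            scores = _cv_scores_batch(X3, y, config)
            values[kchunk] = _measure_batch(scores, y, config.measure)
            pred = np.where(scores >= 0, 1, -1)
            n_correct[kchunk] = (pred == y[None, :]).sum(axis=1)
    return PerformanceMap(values=values, measure=config.measure,
                          smoothed=False, k_total=index.k_total, n_correct=n_correct)


class SearchlightDecoder(BaseEstimator):
    """Scikit-learn style wrapper: fit(X, y) computes the whole-volume map.

    Parameters mirror :class:`CVConfig`; the searchlight index (geometry) is a
    constructor argument because it is data-shape metadata, not a tunable.
    Fitted attributes: ``performance_map_`` and ``values_``.
    """

    def __init__(self, index: SearchlightIndex = None, outer_folds: int = 10,
                 inner_folds: int = 5, c_grid=None, seed: int = 0,
                 measure: str = "auc", stratified: bool = True):
        self.index = index
        self.outer_folds = outer_folds
        self.inner_folds = inner_folds
        self.c_grid = c_grid
        self.seed = seed
        self.measure = measure
        self.stratified = stratified

    def _config(self) -> CVConfig:
        grid = _default_c_grid() if self.c_grid is None else np.asarray(self.c_grid)
        return CVConfig(outer_folds=self.outer_folds, inner_folds=self.inner_folds,
                        c_grid=grid, seed=self.seed, measure=self.measure,
                        stratified=self.stratified)

    def fit(self, X, y):
        if self.index is None:
            raise ValueError("SearchlightDecoder requires a SearchlightIndex")
        trials = TrialSet(activations=np.asarray(X, float), labels=np.asarray(y, int))
        self.performance_map_ = searchlight_map(trials, self.index, self._config())
        self.values_ = self.performance_map_.values
        return self
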