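"""Family-aware penalized brain-behavior prediction.

Feature matrices are assembled from tract profiles in a fixed tract-major
order (tract, then metric, then node), with one penalty group per
(tract, metric) combination -- 24 tracts x 4 metrics x 100 nodes = 9,600
features in 96 groups by default.  Model evaluation uses nested k-fold
cross-validation where subjects of the same family always share a fold, so
familial resemblance can never leak between training and validation data.

Objectives (n = training samples, w = weights, groups g with p_g features):

    LASSO:  1/(2n) ||y - Xw||^2  +  lambda ||w||_1
    SGL:    1/(2n) ||y - Xw||^2
            + lambda [ (1 - a) sum_g sqrt(p_g) ||w_g||_2  +  a ||w||_1 ]

with mixing parameter a (default 0.95).  The LASSO route uses scikit-learn's
coordinate descent (identical objective); the sparse-group objective is
solved in-package by accelerated proximal gradient (FISTA), whose proximal
operator is elementwise soft-thresholding followed by groupwise shrinkage.
With a = 1 the SGL objective reduces exactly to the LASSO.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "CVResult",
    "ModelResult",
    "build_features",
    "accept_external_features",
    "family_folds",
    "fit_penalized_cv",
    "repeat_cv",
    "sgl_fit",
]

DEFAULT_ALPHA_MIX = 0.95
DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 1e-4


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Subjects x features with (tract, metric, node) labels and groups."""

    X: np.ndarray
    feature_info: pd.DataFrame      # columns tract, metric, node
    groups: np.ndarray              # int group id per feature
    group_names: list[str]
    subject_ids: list[str]
    family_ids: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.subject_ids), len(self.feature_info)):
            raise ValueError("X shape inconsistent with labels")
        if len(self.groups) != self.X.shape[1]:
            raise ValueError("groups length inconsistent with feature count")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def group_indices(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.groups == g)
                for g in range(len(self.group_names))]


def build_features(
    profiles,
    family_ids=None,
    group_by: str = "tract_metric",
) -> FeatureMatrix:
    """Flatten tract profiles into a subjects x features matrix.

    Feature order is tract-major, then metric, then node; groups are one per
    (tract, metric) by default (``group_by='tract'`` collapses metrics into
    per-tract groups).  Missing values are imputed by the feature mean with
    a logged count; subjects with no finite features at all are excluded
    with a warning.
    """
    if not profiles:
        raise ValueError("no profiles given")
    ref = profiles[0]
    shape = ref.values.shape
    for p in profiles:
        if p.values.shape != shape or p.tract_names != ref.tract_names \
                or p.metric_names != ref.metric_names:
            raise ValueError("profiles have inconsistent dimensions or labels")

    X = np.stack([p.values.reshape(-1) for p in profiles])
    subject_ids = [p.subject_id for p in profiles]

    usable = np.isfinite(X).any(axis=1)
    if not usable.all():
        dropped = [s for s, u in zip(subject_ids, usable) if not u]
        logger.warning("excluding %d subject(s) with all-missing features: %s",
                       len(dropped), dropped)
        X = X[usable]
        subject_ids = [s for s, u in zip(subject_ids, usable) if u]
        if family_ids is not None:
            family_ids = np.asarray(family_ids)[usable]

    n_missing = int((~np.isfinite(X)).sum())
    if n_missing:
        logger.info("imputing %d missing feature values by feature means",
                    n_missing)
        col_mean = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        X = np.where(np.isfinite(X), X, col_mean)

    k, m, n = shape
    feature_info = pd.DataFrame(
        {
            "tract": np.repeat(ref.tract_names, m * n),
            "metric": np.tile(np.repeat(ref.metric_names, n), k),
            "node": np.tile(np.arange(n), k * m),
        }
    )
    if group_by == "tract_metric":
        groups = np.repeat(np.arange(k * m), n)
        group_names = [f"{t}|{met}" for t in ref.tract_names
                       for met in ref.metric_names]
    elif group_by == "tract":
        groups = np.repeat(np.arange(k), m * n)
        group_names = list(ref.tract_names)
    else:
        raise ValueError("group_by must be 'tract_metric' or 'tract'")
    return FeatureMatrix(
        X, feature_info, groups, group_names, subject_ids,
        None if family_ids is None else np.asarray(family_ids),
    )


def accept_external_features(source, subject_ids,
                             family_ids=None) -> FeatureMatrix:
    """Wrap a precomputed feature table (e.g. local-connectome features).

    ``source`` is a CSV path or array-like with one row per subject in
    ``subject_ids`` order.  All features form a single trivial group, making
    the matrix usable by the LASSO route of :func:`fit_penalized_cv`.
    """
    if isinstance(source, (str,)) or hasattr(source, "read"):
        X = pd.read_csv(source).to_numpy(dtype=float)
    else:
        X = np.asarray(source, dtype=float)
    if X.shape[0] != len(subject_ids):
        raise ValueError(
            f"feature table has {X.shape[0]} rows but {len(subject_ids)} "
            "subjects were given"
        )
    p = X.shape[1]
    feature_info = pd.DataFrame(
        {"tract": ["external"] * p, "metric": ["external"] * p,
         "node": np.arange(p)}
    )
    return FeatureMatrix(
        X, feature_info, np.zeros(p, dtype=int), ["external"],
        list(subject_ids),
        None if family_ids is None else np.asarray(family_ids),
    )


# ---------------------------------------------------------------------------
# Family-grouped folds
# ---------------------------------------------------------------------------

def family_folds(family_ids, k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign subjects to k folds without ever splitting a family.

    Families are shuffled (seeded), stably sorted largest-first by subject
    count, and greedily assigned to the currently smallest fold (ties to the
    lowest fold index), which balances fold sizes.  Returns an int fold id
    per subject.
    """
    family_ids = np.asarray(family_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    fams, inverse = np.unique(family_ids, return_inverse=True)
    if len(fams) < k:
        raise ValueError(f"need at least {k} families, got {len(fams)}")
    sizes = np.bincount(inverse)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(fams))
    order = order[np.argsort(-sizes[order], kind="stable")]
    fold_of_family = np.empty(len(fams), dtype=int)
    fold_sizes = np.zeros(k, dtype=int)
    for f in order:
        target = int(np.argmin(fold_sizes))
        fold_of_family[f] = target
        fold_sizes[target] += sizes[f]
    return fold_of_family[inverse]


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def _sgl_prox(v: np.ndarray, thresh_l1: float, group_slices: list[np.ndarray],
              group_thresh: np.ndarray) -> np.ndarray:
    """Proximal operator of the sparse-group penalty.

    Elementwise soft-thresholding at ``thresh_l1`` followed by group-wise
    L2 shrinkage at ``group_thresh[g]``.
    """
    w = np.sign(v) * np.maximum(np.abs(v) - thresh_l1, 0.0)
    for g, cols in enumerate(group_slices):
        norm = np.linalg.norm(w[cols])
        if norm <= group_thresh[g]:
            w[cols] = 0.0
        elif group_thresh[g] > 0:
            w[cols] *= 1.0 - group_thresh[g] / norm
    return w


def sgl_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    group_indices: list[np.ndarray],
    alpha_mix: float = DEFAULT_ALPHA_MIX,
    w0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    lipschitz: float | None = None,
) -> np.ndarray:
    """Solve the sparse group lasso by FISTA.

    Minimizes 1/(2n)||y - Xw||^2 + lam [(1-a) sum_g sqrt(p_g) ||w_g||_2 +
    a ||w||_1].  ``X`` and ``y`` should be centered (no intercept is fit).
    Convergence when the max absolute weight update falls below
    ``tol * (1 + max|w|)``.
    """
    n, p = X.shape
    if lipschitz is None:
        lipschitz = _spectral_norm_sq(X) / n
    sqrt_pg = np.array([np.sqrt(len(cols)) for cols in group_indices])
    w = np.zeros(p) if w0 is None else w0.copy()
    z = w.copy()
    t = 1.0
    step = 1.0 / max(lipschitz, 1e-300)
    l1 = lam * alpha_mix * step
    gthresh = lam * (1.0 - alpha_mix) * sqrt_pg * step
    for _ in range(max_iter):
        grad = X.T @ (X @ z - y) / n
        w_new = _sgl_prox(z - step * grad, l1, group_indices, gthresh)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = w_new + ((t - 1.0) / t_new) * (w_new - w)
        delta = np.max(np.abs(w_new - w)) if p else 0.0
        w, t = w_new, t_new
        if delta <= tol * (1.0 + np.max(np.abs(w), initial=0.0)):
            break
    return w


def _spectral_norm_sq(X: np.ndarray, n_iter: int = 50) -> float:
    """Largest squared singular value via power iteration (deterministic)."""
    p = X.shape[1]
    v = np.ones(p) / np.sqrt(p)
    s = 0.0
    for _ in range(n_iter):
        u = X.T @ (X @ v)
        s_new = np.linalg.norm(u)
        if s_new == 0:
            return 0.0
        v = u / s_new
        if abs(s_new - s) <= 1e-10 * max(s_new, 1.0):
            s = s_new
            break
        s = s_new
    return float(s)


def _lambda_grid(X, y, alpha_mix, n_lambda, min_ratio) -> np.ndarray:
    lam_max = np.max(np.abs(X.T @ y)) / (len(y) * max(alpha_mix, 1e-3))
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio),
                       n_lambda)


def _fit_path(X, y, lambdas, model, group_indices, alpha_mix,
              tol, max_iter) -> np.ndarray:
    """Coefficients (n_lambda, p) along a descending lambda path, warm started."""
    p = X.shape[1]
    coefs = np.zeros((len(lambdas), p))
    if model == "lasso":
        est = Lasso(alpha=lambdas[0], warm_start=True, max_iter=max_iter,
                    tol=tol, fit_intercept=False)
        for li, lam in enumerate(lambdas):
            est.set_params(alpha=lam)
            est.fit(X, y)
            coefs[li] = est.coef_
    elif model == "sgl":
        lips = _spectral_norm_sq(X) / X.shape[0]
        w = np.zeros(p)
        for li, lam in enumerate(lambdas):
            w = sgl_fit(X, y, lam, group_indices, alpha_mix, w0=w,
                        tol=tol, max_iter=max_iter, lipschitz=lips)
            coefs[li] = w
    else:
        raise ValueError("model must be 'lasso' or 'sgl'")
    return coefs


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """One nested-CV run: pooled and per-fold accuracy plus diagnostics."""

    r2: float                       # pooled out-of-sample R^2
    r2_per_fold: np.ndarray
    predictions: np.ndarray         # out-of-sample prediction per subject
    fold_assign: np.ndarray
    weights: np.ndarray             # (k, p) per-outer-fold, original scale
    intercepts: np.ndarray
    best_lambdas: np.ndarray
    scaler_means: np.ndarray        # (k, p) training-fold standardization
    scaler_stds: np.ndarray

    @property
    def mean_weights(self) -> np.ndarray:
        return self.weights.mean(axis=0)


def _r2(y_true, y_pred) -> float:
    ss_res = np.sum((y_true - y_pred) ** 2)
    ss_tot = np.sum((y_true - np.mean(y_true)) ** 2)
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_penalized_cv(
    features: FeatureMatrix,
    y: np.ndarray,
    model: str = "lasso",
    k: int = 5,
    seed: int = 0,
    alpha_mix: float = DEFAULT_ALPHA_MIX,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    tol: float = 1e-5,
    max_iter: int = 2000,
) -> CVResult:
    """Nested family-grouped k-fold CV with an inner lambda search.

    Outer loop: k folds that never split a family.  Per outer fold, features
    are standardized on the training subjects only; an inner family-grouped
    k-fold selects lambda from a log-spaced grid by mean validation R^2; the
    model is refit on the whole outer-training set at the selected lambda
    and predicts the held-out fold.  Pooled out-of-sample predictions give
    the headline R^2 (per-fold R^2 values are also reported).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    if features.family_ids is None:
        raise ValueError("features need family_ids for family-grouped CV")
    X = features.X
    group_indices = features.group_indices() if model == "sgl" else None

    folds = family_folds(features.family_ids, k=k, seed=seed)
    inner_seeds = np.random.SeedSequence(seed).generate_state(k) % (2**31 - 1)

    preds = np.empty_like(y)
    r2_folds = np.empty(k)
    p = X.shape[1]
    weights = np.zeros((k, p))
    intercepts = np.zeros(k)
    best_lambdas = np.zeros(k)
    means = np.zeros((k, p))
    stds = np.zeros((k, p))

    for f in range(k):
        tr = folds != f
        te = ~tr
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        means[f], stds[f] = mu, sd
        Xtr = (X[tr] - mu) / sd
        y_mean = y[tr].mean()
        ytr = y[tr] - y_mean

        lambdas = _lambda_grid(Xtr, ytr, alpha_mix if model == "sgl" else 1.0,
                               n_lambda, lambda_min_ratio)
        inner = family_folds(features.family_ids[tr], k=k,
                             seed=int(inner_seeds[f]))
        val_sse = np.zeros(len(lambdas))
        val_sst = np.zeros(len(lambdas))
        for g in range(k):
            itr = inner != g
            ite = ~itr
            imu = Xtr[itr].mean(axis=0)
            isd = Xtr[itr].std(axis=0)
            isd = np.where(isd > 0, isd, 1.0)
            Xi = (Xtr[itr] - imu) / isd
            yi_mean = ytr[itr].mean()
            yi = ytr[itr] - yi_mean
            coefs = _fit_path(Xi, yi, lambdas, model, group_indices,
                              alpha_mix, tol, max_iter)
            Xv = (Xtr[ite] - imu) / isd
            pv = Xv @ coefs.T + yi_mean
            resid = ytr[ite][:, None] - pv
            val_sse += (resid**2).sum(axis=0)
            val_sst += np.sum((ytr[ite] - ytr[ite].mean()) ** 2)
        best = int(np.argmin(val_sse))
        best_lambdas[f] = lambdas[best]
        coefs = _fit_path(Xtr, ytr, lambdas[: best + 1], model, group_indices,
                          alpha_mix, tol, max_iter)
        w_std = coefs[-1]
        preds[te] = ((X[te] - mu) / sd) @ w_std + y_mean
        r2_folds[f] = _r2(y[te], preds[te])
        weights[f] = w_std / sd
        intercepts[f] = y_mean - (mu / sd) @ w_std

    return CVResult(
        r2=_r2(y, preds),
        r2_per_fold=r2_folds,
        predictions=preds,
        fold_assign=folds,
        weights=weights,
        intercepts=intercepts,
        best_lambdas=best_lambdas,
        scaler_means=means,
        scaler_stds=stds,
    )


# ---------------------------------------------------------------------------
# Repeated CV and weight stability
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    """Accuracy distribution and weight-stability summary over CV repeats."""

    model: str
    r2_per_repeat: np.ndarray
    weights_per_repeat: np.ndarray      # (n_repeats, p) fold-averaged
    mean_weights: np.ndarray
    weight_ci_low: np.ndarray
    weight_ci_high: np.ndarray
    weight_variance: np.ndarray          # per feature, across repeats
    weight_variance_summary: float       # mean across features
    feature_info: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2_per_repeat))

    def results_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"repeat": np.arange(len(self.r2_per_repeat)),
             "r2": self.r2_per_repeat}
        )

    def weights_dataframe(self) -> pd.DataFrame:
        df = self.feature_info.copy()
        df["mean_weight"] = self.mean_weights
        df["ci_low"] = self.weight_ci_low
        df["ci_high"] = self.weight_ci_high
        return df


def repeat_cv(
    features: FeatureMatrix,
    y: np.ndarray,
    model: str = "lasso",
    n_repeats: int = 100,
    seed: int = 0,
    seeds=None,
    **cv_kwargs,
) -> ModelResult:
    """Repeat the full nested CV with distinct fold splits.

    Each repeat reruns :func:`fit_penalized_cv` with its own fold seed
    (``seeds`` overrides the derived sequence; passing the same seed twice
    reproduces identical repeats).  The per-repeat weight vector is the mean
    of the outer-fold weights on the original feature scale; the
    weight-variance summary is the across-repeat variance of each weight,
    averaged over features -- the quantity on which sparse-group and plain
    L1 models are compared.
    """
    if n_repeats < 2 and seeds is None:
        raise ValueError("n_repeats must be >= 2")
    if seeds is None:
        seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (
            2**31 - 1
        )
    seeds = [int(s) for s in seeds]
    r2s = np.empty(len(seeds))
    weights = np.zeros((len(seeds), features.n_features))
    for r, s in enumerate(seeds):
        res = fit_penalized_cv(features, y, model=model, seed=s, **cv_kwargs)
        r2s[r] = res.r2
        weights[r] = res.mean_weights
    var = weights.var(axis=0, ddof=1) if len(seeds) > 1 else np.zeros(
        features.n_features
    )
    return ModelResult(
        model=model,
        r2_per_repeat=r2s,
        weights_per_repeat=weights,
        mean_weights=weights.mean(axis=0),
        weight_ci_low=np.percentile(weights, 2.5, axis=0),
        weight_ci_high=np.percentile(weights, 97.5, axis=0),
        weight_variance=var,
        weight_variance_summary=float(var.mean()),
        feature_info=features.feature_info,
    )
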