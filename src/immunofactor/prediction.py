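"""Outcome labeling, ROC evaluation and penalized logistic prediction.

Outcome is defined from the change in left-ventricular ejection fraction
(ΔEF) between admission and follow-up; cohorts differ in how a *stable*
ΔEF is treated, which :class:`OutcomeRule` encodes explicitly rather than
harmonizing away.  Factor scores or feature values at the first
timepoint are min–max scaled and evaluated by ROC AUC; transferable
classifiers use L1-penalized (lasso) logistic regression tuned by k-fold
cross-validated binomial deviance (the ``lambda.min`` convention), or a
plain maximum-likelihood logistic model for small hand-picked feature
sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger("immunofactor.prediction")


class SeparationError(RuntimeError):
    """Perfect separation: unpenalized logistic MLE does not exist."""


@dataclass
class OutcomeRule:
    """Sign-of-ΔEF labeling; ``stable_is`` decides ΔEF == 0.

    The discovery cohort counts stable ΔEF as good outcome, the
    validation cohort as poor; both are preserved verbatim.
    """

    stable_is: str  # 'good' or 'poor'

    def __post_init__(self) -> None:
        if self.stable_is not in ("good", "poor"):
            raise ValueError("stable_is must be 'good' or 'poor'")

    def label(self, delta_ef: float) -> str:
        if pd.isna(delta_ef):
            return "unknown"
        if delta_ef > 0:
            return "good"
        if delta_ef < 0:
            return "poor"
        return self.stable_is


MUNICH_RULE = OutcomeRule(stable_is="good")
GRONINGEN_RULE = OutcomeRule(stable_is="poor")


def label_outcome(meta: pd.DataFrame, rule: OutcomeRule) -> pd.Series:
    """Per-sample outcome labels from ΔEF; 'unknown' where ΔEF is absent."""
    return meta.set_index("sample_id")["delta_EF"].map(rule.label).rename("outcome")


def minmax_scale(values) -> np.ndarray:
    """(x - min) / (max - min); constant input maps to all 0.5 with a warning."""
    x = np.asarray(values, float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        warnings.warn("minmax_scale: constant input, returning 0.5", stacklevel=2)
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """ROC AUC (= P(score_pos > score_neg) + 0.5 P(tie)) and curve points."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, float)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc needs both classes present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# penalized logistic regression


@dataclass
class PenalizedLogisticModel:
    coefficients: pd.Series  # original feature scale
    intercept: float
    lambda_path: np.ndarray
    cv_deviance: np.ndarray  # folds x lambdas
    lambda_min: float
    feature_means: pd.Series
    feature_sds: pd.Series
    seed: int

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.intercept + X[self.coefficients.index].to_numpy(float) @ \
            self.coefficients.to_numpy(float)
        return 1.0 / (1.0 + np.exp(-eta))


def lambda_max(X_std: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty zeroing every coefficient (KKT): max|X'(y-ybar)|/n."""
    n = len(y)
    return float(np.max(np.abs(X_std.T @ (y - y.mean()))) / n)


def _fold_assignment(y: np.ndarray, n_folds: int, seed: int,
                     stratified: bool) -> np.ndarray:
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    if stratified:
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            folds[idx] = np.arange(len(idx)) % n_folds
    else:
        idx = rng.permutation(len(y))
        folds[idx] = np.arange(len(y)) % n_folds
    return folds


def _l1_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                 beta: np.ndarray, b0: float, tol: float = 1e-7,
                 max_outer: int = 100) -> tuple[np.ndarray, float]:
    """One L1-penalized logistic fit by IRLS + coordinate descent.

    Minimizes ``-(1/n) loglik + lam * ||beta||_1`` (intercept unpenalized):
    an outer quadratic approximation around the current linear predictor
    and inner cyclic coordinate descent with soft thresholding, which
    yields exact zeros and satisfies the KKT conditions at convergence.
    """
    n, p = X.shape
    beta = beta.copy()

    def cd_pass(w: np.ndarray, z: np.ndarray, r: np.ndarray, b0: float,
                active: np.ndarray) -> tuple[float, float]:
        max_delta = 0.0
        b0_new = b0 + float(np.sum(w * r) / np.sum(w))
        max_delta = abs(b0_new - b0)
        r += b0 - b0_new
        for j in active:
            xj = X[:, j]
            rho = float(np.sum(w * xj * (r + xj * beta[j]))) / n
            denom = float(np.sum(w * xj * xj)) / n
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / denom
            if new != beta[j]:
                r += xj * (beta[j] - new)
                max_delta = max(max_delta, abs(new - beta[j]))
                beta[j] = new
        return b0_new, max_delta

    all_j = np.arange(p)
    for _ in range(max_outer):
        eta = b0 + X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-5, None)
        z = eta + (y - mu) / w
        beta_old, b0_old = beta.copy(), b0
        for _ in range(100):
            # full pass to fix the active set, then iterate it to convergence
            r = z - b0 - X @ beta
            b0, delta = cd_pass(w, z, r, b0, all_j)
            if delta < tol:
                break
            active = np.flatnonzero(beta != 0.0)
            for _ in range(100):
                b0, delta = cd_pass(w, z, r, b0, active)
                if delta < tol:
                    break
        if max(abs(b0 - b0_old), float(np.max(np.abs(beta - beta_old), initial=0.0))) < tol:
            break
    return beta, b0


def _l1_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
             dev_stop: float = 0.99) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients along a decreasing lambda path, warm-started.

    The path stops early once the training deviance is essentially
    saturated (fraction ``dev_stop`` of the null deviance explained) —
    beyond that point the training data are (near-)separated and smaller
    penalties only inflate coefficient norms; remaining path entries
    carry the last solved solution forward.
    """
    p = X.shape[1]
    coefs = np.zeros((len(lambdas), p))
    icepts = np.zeros(len(lambdas))
    beta = np.zeros(p)
    ybar = float(y.mean())
    b0 = float(np.log(ybar / (1.0 - ybar)))
    null_dev = binomial_deviance(y, np.full_like(y, ybar, dtype=float))
    for i, lam in enumerate(lambdas):
        beta, b0 = _l1_logistic(X, y, float(lam), beta, b0, max_outer=30)
        coefs[i] = beta
        icepts[i] = b0
        dev = binomial_deviance(y, 1.0 / (1.0 + np.exp(-(b0 + X @ beta))))
        if dev < (1.0 - dev_stop) * null_dev:
            coefs[i + 1:] = beta
            icepts[i + 1:] = b0
            break
    return coefs, icepts


def binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_lasso_logistic(X: pd.DataFrame, y, n_folds: int = 8, seed: int = 0,
                       n_lambda: int = 100, lambda_min_ratio: float = 1e-4,
                       stratified: bool = True) -> PenalizedLogisticModel:
    """Cross-validated L1 logistic regression, ``lambda.min`` selection.

    Features are standardized internally; the penalty path runs
    log-spaced from lambda_max (the smallest penalty that zeroes every
    coefficient) down to ``lambda_min_ratio * lambda_max``.  Fold
    assignment is deterministic given ``seed`` and stratified by class by
    default (a stabilizing choice at the small sample sizes this is used
    at; pass ``stratified=False`` for plain random folds).  The model is
    refit on all data at the deviance-minimizing penalty and coefficients
    are reported on the original feature scale.
    """
    Xdf = pd.DataFrame(X)
    yv = np.asarray(y).astype(int)
    if len(np.unique(yv)) < 2:
        raise ValueError("y must contain both classes")
    if len(yv) < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples")
    mu = Xdf.mean(axis=0)
    sd = Xdf.std(axis=0, ddof=0).replace(0.0, 1.0)
    Xs = ((Xdf - mu) / sd).to_numpy(float)

    lmax = lambda_max(Xs, yv)
    lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
    folds = _fold_assignment(yv, n_folds, seed, stratified)

    cv_dev = np.full((n_folds, n_lambda), np.nan)
    for f in range(n_folds):
        train, test = folds != f, folds == f
        if len(np.unique(yv[train])) < 2:
            continue
        coefs, icepts = _l1_path(Xs[train], yv[train], lambdas)
        eta = Xs[test] @ coefs.T + icepts
        probs = 1.0 / (1.0 + np.exp(-eta))
        for i in range(n_lambda):
            cv_dev[f, i] = binomial_deviance(yv[test], probs[:, i])
    mean_dev = np.nanmean(cv_dev, axis=0)
    best = int(np.argmin(mean_dev))
    lam_min = float(lambdas[best])

    coefs, icepts = _l1_path(Xs, yv, lambdas[: best + 1])
    beta_std = coefs[best]
    beta = beta_std / sd.to_numpy(float)
    intercept = float(icepts[best] - np.sum(beta * mu.to_numpy(float)))
    return PenalizedLogisticModel(
        coefficients=pd.Series(beta, index=Xdf.columns),
        intercept=intercept, lambda_path=lambdas, cv_deviance=cv_dev,
        lambda_min=lam_min, feature_means=mu, feature_sds=sd, seed=seed,
    )


def fit_logistic(X, y, tol: float = 1e-8, max_iter: int = 200) -> pd.Series:
    """Unpenalized logistic regression by IRLS; errors on separation.

    Returns coefficients indexed by 'intercept' then feature names.
    """
    Xdf = pd.DataFrame(X)
    yv = np.asarray(y).astype(float)
    design = sm.add_constant(Xdf.to_numpy(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(yv, design, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=max_iter, tol=tol)
        except Exception as exc:  # statsmodels raises on hard separation
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e3:
        raise SeparationError("perfect separation detected: coefficient norms diverge")
    fitted = 1.0 / (1.0 + np.exp(-design @ params))
    if np.all((fitted > 0.5) == (yv > 0.5)) and binomial_deviance(yv, fitted) < 1e-6:
        raise SeparationError("perfect separation detected: zero training deviance")
    return pd.Series(params, index=["intercept", *Xdf.columns])


def select_top_intersection(rankA: pd.Series, rankB: pd.Series, n: int = 280) -> set[str]:
    """Intersection of the top-n features (by |weight|) of two rankings."""
    topA = set(rankA.abs().sort_values(ascending=False, kind="stable").index[:n])
    topB = set(rankB.abs().sort_values(ascending=False, kind="stable").index[:n])
    return topA & topB
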