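"""Multi-view (group) factor analysis with ARD, fit by EM.

Model, per sample n and view m (of D_m features):

    y_nm = W_m z_n + eps_m,   eps_m ~ N(0, tau_m^{-1} I),   z_n ~ N(0, I_K)

with an automatic-relevance-determination (ARD) prior on the columns of
each W_m: W_m[:, k] ~ N(0, alpha_{mk}^{-1} I).  Per-(view, factor)
precisions alpha shrink factor-view pairs that carry no signal toward
zero weight, so the variance decomposition cleanly separates active from
inactive pairs.  Samples may be absent from individual views; an absent
row simply contributes nothing to that view's sufficient statistics.

Estimation is maximum a posteriori EM with the factor scores Z as the
latent variable: the E-step computes the exact Gaussian posterior of z_n
given the sample's observed views, the M-step updates W_m, tau_m and
alpha_{mk} in closed form.  Initialization is deterministic (SVD of the
concatenated, per-view-scaled data with absent entries at zero), so a fit
is bit-reproducible; the tracked objective is the negative log joint
(marginal likelihood of Y plus the ARD prior on W), which the EM updates
do not increase.

After convergence, factors are ordered by total variance explained and
given a sign convention (the largest-|weight| feature of each factor is
positive), so factor indices are comparable across runs and cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, log, pi

import numpy as np
import pandas as pd

from .io import MultiViewDataset

_LOG2PI = log(2.0 * pi)


@dataclass
class FactorModelFit:
    """Fitted group factor model: scores, weights, precisions, trace."""

    Z: np.ndarray  # samples x K
    W: dict[str, np.ndarray]  # view -> features x K
    tau: dict[str, float]  # view -> noise precision
    alpha: dict[str, np.ndarray]  # view -> K ARD precisions
    trace: list[float]
    K: int
    sample_ids: list[str]
    view_names: list[str]
    feature_ids: dict[str, list[str]]
    variance_table: pd.DataFrame | None = None

    def qualified_weights(self) -> pd.DataFrame:
        """All views' weights stacked, indexed by ``view::feature``."""
        frames = []
        for name in self.view_names:
            frames.append(pd.DataFrame(
                self.W[name],
                index=[f"{name}::{f}" for f in self.feature_ids[name]],
                columns=[f"F{k + 1}" for k in range(self.K)],
            ))
        return pd.concat(frames)


def _extract_views(dataset: MultiViewDataset):
    names, Ys, masks, feats = [], [], [], {}
    for name, v in dataset.views.items():
        names.append(name)
        Y = v.values.to_numpy(float)
        mask = v.mask.to_numpy(bool) if v.mask is not None else ~np.isnan(Y).all(axis=1)
        if np.isnan(Y[mask]).any():
            raise ValueError(f"view '{name}' has non-finite entries in present rows")
        Ys.append(Y)
        masks.append(mask)
        feats[name] = list(v.values.columns)
    return names, Ys, masks, feats


def fit_gfa(dataset: MultiViewDataset, K: int = 20, max_iter: int = 50_000,
            tol: float = 1e-6, seed: int = 0,
            min_iter: int = 10, check_every: int = 50) -> FactorModelFit:
    """Fit the ARD group factor model to an inverse-normal-transformed dataset.

    Parameters
    ----------
    dataset
        Aligned views on a shared sample universe; present rows must be
        finite (run the inverse normal transform first).
    K
        Number of factors; must not exceed the sample count or any view's
        feature count.
    max_iter, tol, check_every
        EM stops when the objective's relative change over the last
        ``check_every`` iterations falls below ``tol``, or after
        ``max_iter`` iterations.  The windowed criterion suits the long
        shallow tail of ARD-EM, where per-iteration changes are tiny long
        before the factor rotation has settled.
    seed
        Accepted for interface uniformity; the fit is deterministic
        (SVD-based initialization), so the seed does not alter the result.
    """
    names, Ys, masks, feats = _extract_views(dataset)
    n = len(dataset.meta)
    Ds = [Y.shape[1] for Y in Ys]
    # K may exceed a single view's feature count (that view simply cannot
    # host K independent directions) but not the sample count or the total
    # feature count, where the model would be vacuous.
    if K > n or K > sum(Ds):
        raise ValueError(
            f"K={K} exceeds the sample count ({n}) or the total feature count "
            f"({sum(Ds)})"
        )
    M = len(names)
    Y0 = [np.where(np.isnan(Y), 0.0, Y) for Y in Ys]  # absent rows zeroed

    # deterministic init: SVD of concatenated per-view-scaled data
    X = np.hstack([Y0[m] / np.sqrt(Ds[m]) for m in range(M)])
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    MU = U[:, :K] * s[:K]
    MU = MU / max(MU.std(), 1e-12)

    W = []
    tau = np.empty(M)
    for m in range(M):
        obs = masks[m]
        A = MU[obs].T @ MU[obs] + 1e-6 * np.eye(K)
        W.append(np.linalg.solve(A, MU[obs].T @ Y0[m][obs]).T)
        resid = Y0[m][obs] - MU[obs] @ W[m].T
        tau[m] = 1.0 / max(resid.var(), 1e-8)
    alpha = np.ones((M, K))

    ALPHA_MAX, TAU_MAX = 1e8, 1e8
    pattern = np.vstack(masks).T  # n x M
    pat_keys, pat_inv = np.unique(pattern, axis=0, return_inverse=True)

    sq_norms = np.array([float((Y0[m] ** 2).sum()) for m in range(M)])
    trace: list[float] = []
    prev = np.inf
    Sig_list: list[np.ndarray] = []
    for it in range(max_iter):
        # --- E-step: posterior of z per observed-view pattern
        G = [tau[m] * (W[m].T @ W[m]) for m in range(M)]
        Sig_list = []
        logdet_prec = np.empty(len(pat_keys))
        for p, key in enumerate(pat_keys):
            P = np.eye(K) + sum(G[m] for m in range(M) if key[m])
            Sig_list.append(np.linalg.inv(P))
            sign_, ld = np.linalg.slogdet(P)
            logdet_prec[p] = ld
        B = np.zeros((n, K))
        for m in range(M):
            B += tau[m] * (Y0[m] @ W[m])
        MU = np.empty((n, K))
        for p in range(len(pat_keys)):
            rows = pat_inv == p
            MU[rows] = B[rows] @ Sig_list[p]

        # --- objective: -log p(Y | W, tau) - log p(W | alpha) (+ consts)
        quad = (tau * sq_norms).sum() - float((B * MU).sum())
        nll = 0.0
        for p, key in enumerate(pat_keys):
            cnt = int((pat_inv == p).sum())
            dim = sum(Ds[m] for m in range(M) if key[m])
            ltau = sum(Ds[m] * log(tau[m]) for m in range(M) if key[m])
            nll += cnt * (dim * _LOG2PI - ltau + logdet_prec[p])
        nll = 0.5 * (nll + quad)
        wpen = 0.0
        for m in range(M):
            nrm2 = (W[m] ** 2).sum(axis=0)
            wpen += 0.5 * float((alpha[m] * nrm2 - Ds[m] * np.log(alpha[m])).sum())
        obj = nll + wpen
        trace.append(obj)
        if it >= max(min_iter, check_every) and it % check_every == 0:
            ref = trace[-1 - check_every]
            if abs(ref - obj) <= tol * abs(ref):
                break

        # --- M-step
        for m in range(M):
            obs = masks[m]
            rows = np.flatnonzero(obs)
            A = MU[rows].T @ MU[rows]
            for p, key in enumerate(pat_keys):
                if key[m]:
                    A += int(((pat_inv == p) & obs).sum()) * Sig_list[p]
            C = Y0[m][rows].T @ MU[rows]
            W[m] = np.linalg.solve((A + np.diag(alpha[m]) / tau[m]).T, C.T).T
            # noise precision from the expected residual sum of squares
            ess = float(((Y0[m][rows] - MU[rows] @ W[m].T) ** 2).sum())
            WtW = W[m].T @ W[m]
            for p, key in enumerate(pat_keys):
                if key[m]:
                    cnt = int(((pat_inv == p) & obs).sum())
                    ess += cnt * float((WtW * Sig_list[p]).sum())
            tau[m] = min(len(rows) * Ds[m] / max(ess, 1e-300), TAU_MAX)
            alpha[m] = np.minimum(Ds[m] / np.maximum((W[m] ** 2).sum(axis=0), 1e-300),
                                  ALPHA_MAX)

    fit = FactorModelFit(
        Z=MU, W={names[m]: W[m] for m in range(M)},
        tau={names[m]: float(tau[m]) for m in range(M)},
        alpha={names[m]: alpha[m].copy() for m in range(M)},
        trace=trace, K=K,
        sample_ids=list(dataset.meta["sample_id"]),
        view_names=names, feature_ids=feats,
    )
    _order_and_sign(fit, Ys, masks)
    fit.variance_table = variance_explained(fit, dataset)
    return fit


def _order_and_sign(fit: FactorModelFit, Ys, masks) -> None:
    """Order factors by total explained SS, enforce the sign convention."""
    K = fit.K
    explained = np.zeros(K)
    for m, name in enumerate(fit.view_names):
        obs = masks[m]
        Y = np.where(np.isnan(Ys[m]), 0.0, Ys[m])[obs]
        for k in range(K):
            rec = np.outer(fit.Z[obs, k], fit.W[name][:, k])
            explained[k] += (Y ** 2).sum() - ((Y - rec) ** 2).sum()
    order = np.argsort(-explained, kind="stable")
    fit.Z = fit.Z[:, order]
    for name in fit.view_names:
        fit.W[name] = fit.W[name][:, order]
        fit.alpha[name] = fit.alpha[name][order]
    # sign: the single largest-|weight| feature of each factor is positive
    for k in range(K):
        best_val = 0.0
        for name in fit.view_names:
            col = fit.W[name][:, k]
            j = int(np.argmax(np.abs(col)))
            if abs(col[j]) > abs(best_val):
                best_val = col[j]
        if best_val < 0:
            fit.Z[:, k] *= -1.0
            for name in fit.view_names:
                fit.W[name][:, k] *= -1.0


def best_matching_factor(fit: FactorModelFit,
                         target_scores: np.ndarray) -> tuple[int, float]:
    """Fitted factor most correlated with a reference score vector.

    Pruned factors (near-constant scores) yield undefined correlations and
    are treated as zero.  Returns the factor index and the signed
    correlation, which also supplies the sign alignment.
    """
    target = np.asarray(target_scores, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corrs = np.array([np.corrcoef(fit.Z[:, k], target)[0, 1]
                          for k in range(fit.K)])
    corrs = np.nan_to_num(corrs)
    k = int(np.abs(corrs).argmax())
    return k, float(corrs[k])


def active_factors(fit: FactorModelFit, tol: float = 1e-8) -> list[int]:
    """Indices of factors the ARD prior did not prune to zero weight."""
    keep = []
    for k in range(fit.K):
        norm = sum(float(np.linalg.norm(fit.W[n][:, k])) for n in fit.view_names)
        if norm > tol:
            keep.append(k)
    return keep


def variance_explained(fit: FactorModelFit, dataset: MultiViewDataset) -> pd.DataFrame:
    """Fraction of each view's (uncentered) variance explained per factor.

    Entry (k, m) is ``1 - ||Y_m - z_k w_mk^T||^2 / ||Y_m||^2`` over the
    view's present entries; the ``total`` row uses the full K-factor
    reconstruction.  Uncentered sums of squares are appropriate because
    model inputs are inverse-normal transformed (feature means ~ 0).
    """
    rows = {}
    totals = {}
    for name in fit.view_names:
        v = dataset.views[name]
        Y = v.values.to_numpy(float)
        obs = v.mask.to_numpy(bool) if v.mask is not None else ~np.isnan(Y).all(axis=1)
        Yo = Y[obs]
        Yo = np.where(np.isnan(Yo), 0.0, Yo)
        denom = float((Yo ** 2).sum())
        Wm = fit.W[name]
        Zo = fit.Z[obs]
        fr = []
        for k in range(fit.K):
            rec = np.outer(Zo[:, k], Wm[:, k])
            fr.append(1.0 - ((Yo - rec) ** 2).sum() / denom)
        rows[name] = fr
        full = Zo @ Wm.T
        totals[name] = 1.0 - float(((Yo - full) ** 2).sum()) / denom
    table = pd.DataFrame(rows, index=[f"F{k + 1}" for k in range(fit.K)])
    table.loc["total"] = pd.Series(totals)
    table.index.name = "factor"
    return table


def rank_features(fit: FactorModelFit, factor: int,
                  fraction: float = 0.01) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top features of a factor by absolute weight, pooled across views.

    Returns the top ``ceil(fraction * n_features)`` features with their
    signed weights, plus a per-view summary (absolute count among the top
    set and that count relative to the view's own feature number).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    weights = fit.qualified_weights().iloc[:, factor]
    n_top = ceil(fraction * len(weights))
    top = weights.reindex(weights.abs().sort_values(ascending=False, kind="stable").index)
    top = top.iloc[:n_top]
    table = pd.DataFrame({
        "feature": top.index,
        "view": [f.split("::", 1)[0] for f in top.index],
        "weight": top.to_numpy(),
    })
    per_view = []
    for name in fit.view_names:
        cnt = int((table["view"] == name).sum())
        per_view.append((name, cnt, cnt / len(fit.feature_ids[name])))
    counts = pd.DataFrame(per_view, columns=["view", "count", "relative_count"])
    return table.reset_index(drop=True), counts


def group_effect_size(view_values: pd.DataFrame,
                      design_labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-feature OLS slope on a two-level indicator, with standard error.

    The slope of value on the 0/1 group indicator equals the difference of
    group means; the standard error is the usual OLS one with pooled
    residual variance (n - 2 degrees of freedom).
    """
    labels = pd.Series(np.asarray(design_labels), index=view_values.index)
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"design must have exactly two levels, got {levels}")
    g0 = view_values.loc[labels == levels[0]]
    g1 = view_values.loc[labels == levels[1]]
    n0, n1 = len(g0), len(g1)
    if n0 < 2 or n1 < 2:
        raise ValueError("each group needs at least 2 samples")
    slope = g1.mean(axis=0) - g0.mean(axis=0)
    ss = ((g0 - g0.mean(axis=0)) ** 2).sum(axis=0) + ((g1 - g1.mean(axis=0)) ** 2).sum(axis=0)
    sigma2 = ss / (n0 + n1 - 2)
    se = np.sqrt(sigma2 * (1.0 / n0 + 1.0 / n1))
    return pd.DataFrame({"slope": slope, "se": se})
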