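"""Cross-cohort factor transfer via the right inverse of the weight matrix.

A model fitted on a source cohort defines factors through its weight
matrix W (K x D).  A target cohort preprocessed with the *source* recipe
and restricted to the matched features can be projected onto those same
factors without re-estimation:

    Z_target = Y_target @ W^T @ (W W^T)^{-1}

i.e. the Moore–Penrose right inverse of a full-row-rank W, which satisfies
W W^+ = I so an exact linear combination Y = Z0 W recovers Z0 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gfa import FactorModelFit
from .io import MultiViewDataset


@dataclass
class ProjectionInput:
    """Matched weights and target data sharing one feature order."""

    W_matched: np.ndarray  # K x D
    Y_target: pd.DataFrame  # samples x D, columns aligned with W_matched
    feature_ids: list[str]
    match_report: pd.DataFrame


def match_features(model: FactorModelFit, target: MultiViewDataset,
                   view_whitelist: list[str] | None = None,
                   view_map: dict[str, str] | None = None) -> ProjectionInput:
    """Intersect model features with the target cohort by exact id.

    Features are identified as ``view::name``; ``view_map`` optionally
    renames target views onto source view names first (the interface for
    harmonizing cluster annotations between cohorts).  Unmatched features
    are dropped from W; a per-view report of matched/unmatched counts is
    returned alongside.
    """
    view_map = view_map or {}
    target_views = {view_map.get(n, n): v for n, v in target.views.items()}
    whitelist = view_whitelist if view_whitelist is not None else list(model.view_names)

    cols: list[str] = []
    blocks: list[np.ndarray] = []
    frames: list[pd.DataFrame] = []
    report = []
    for name in model.view_names:
        model_feats = model.feature_ids[name]
        if name not in whitelist or name not in target_views:
            report.append((name, 0, len(model_feats)))
            continue
        tv = target_views[name]
        present = [f for f in model_feats if f in set(tv.feature_ids)]
        report.append((name, len(present), len(model_feats) - len(present)))
        if not present:
            continue
        idx = [model_feats.index(f) for f in present]
        blocks.append(model.W[name][idx, :])
        vals = tv.values[present]
        if tv.mask is not None:
            vals = vals.loc[tv.mask[tv.mask].index]
        frames.append(vals.rename(columns={f: f"{name}::{f}" for f in present}))
        cols.extend(f"{name}::{f}" for f in present)
    if not blocks:
        raise ValueError("no model feature matched the target cohort in any view")
    W = np.vstack(blocks).T  # K x D
    Y = pd.concat(frames, axis=1, join="inner")[cols]
    rep = pd.DataFrame(report, columns=["view", "matched", "unmatched"])
    return ProjectionInput(W_matched=W, Y_target=Y, feature_ids=cols, match_report=rep)


def right_inverse(W: np.ndarray, cond_max: float = 1e10) -> np.ndarray:
    """W^T (W W^T)^{-1} for a K x D full-row-rank W, with a condition guard."""
    WWt = W @ W.T
    cond = np.linalg.cond(WWt)
    if not np.isfinite(cond) or cond > cond_max:
        raise ValueError(
            f"W W^T condition number {cond:.3g} exceeds {cond_max:.1g}; "
            "review the feature matching before projecting"
        )
    return W.T @ np.linalg.inv(WWt)


def project_factors(inp: ProjectionInput, cond_max: float = 1e10) -> pd.DataFrame:
    """Project target samples onto source factors: Z = Y W^T (W W^T)^{-1}."""
    Y = inp.Y_target.to_numpy(float)
    if np.isnan(Y).any():
        raise ValueError("target data contain missing entries; preprocess with the "
                         "source recipe (which imputes or masks) before projecting")
    Z = Y @ right_inverse(inp.W_matched, cond_max=cond_max)
    K = inp.W_matched.shape[0]
    return pd.DataFrame(Z, index=inp.Y_target.index,
                        columns=[f"F{k + 1}" for k in range(K)])


def summarize_trajectory(Z: pd.DataFrame, meta: pd.DataFrame, factor: int,
                         reference_means: pd.Series | None = None) -> pd.DataFrame:
    """Per (group, timepoint) mean ± SEM of one factor's scores.

    If ``reference_means`` (a per-timepoint mean profile from the source
    cohort) is given and correlates negatively with the target profile,
    the summarized factor is sign-flipped so trajectories are comparable.
    """
    col = Z.columns[factor]
    df = meta.set_index("sample_id").join(Z[[col]], how="inner")
    out = (df.groupby(["group", "timepoint"], observed=True)[col]
             .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0,
                  n="size")
             .reset_index())
    out["single_sample"] = out["n"] == 1
    if reference_means is not None:
        tp_means = out.groupby("timepoint", observed=True)["mean"].mean()
        common = tp_means.index.intersection(reference_means.index)
        if len(common) >= 2:
            r = np.corrcoef(tp_means[common], reference_means[common])[0, 1]
            if np.isfinite(r) and r < 0:
                out["mean"] = -out["mean"]
    return out
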