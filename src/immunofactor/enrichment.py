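"""Pathway enrichment on factor weights with a rank-sum statistic.

Gene-set annotations (GMT files keyed by gene symbol) are extended to the
pooled multi-view feature space: a feature ``view::gene`` belongs to a
pathway iff its gene symbol is annotated, so one gene can contribute a
feature per view.  Pathways with poor coverage of their gene set among
the measured features are removed, and the remaining ones are tested with
a two-sided Wilcoxon rank-sum of pathway-feature scores against all other
features, separately for positive weights, negative weights and absolute
weights, with Benjamini–Hochberg adjustment per direction.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("immunofactor.enrichment")

DIRECTIONS = ("positive", "negative", "all")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene...; skips empties."""
    pathways: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            continue
        genes = {g for g in parts[2:] if g}
        if genes:
            pathways[parts[0]] = genes
    return pathways


def write_gmt(pathways: dict[str, set[str]], path: str | Path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(sorted(genes))
             for name, genes in pathways.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def feature_gene(feature_id: str) -> str:
    """Gene-symbol component of a ``view::gene`` feature id."""
    return feature_id.split("::", 1)[1] if "::" in feature_id else feature_id


def extend_annotation(pathways: dict[str, set[str]],
                      features: list[str]) -> tuple[dict[str, set[str]], dict[str, float]]:
    """Map gene-level pathways onto the multi-view feature space.

    Returns per pathway the assigned feature set (a gene hits once per
    view it appears in) and the coverage: the fraction of the pathway's
    genes present anywhere among the features.
    """
    by_gene: dict[str, list[str]] = {}
    for f in features:
        by_gene.setdefault(feature_gene(f), []).append(f)
    extended: dict[str, set[str]] = {}
    coverage: dict[str, float] = {}
    for name, genes in pathways.items():
        hit_genes = genes & by_gene.keys()
        extended[name] = {f for g in hit_genes for f in by_gene[g]}
        coverage[name] = len(hit_genes) / len(genes)
    return extended, coverage


def filter_by_coverage(extended: dict[str, set[str]], coverage: dict[str, float],
                       min_coverage: float = 0.2) -> dict[str, set[str]]:
    """Drop pathways whose gene coverage is strictly below the threshold."""
    kept = {n: fs for n, fs in extended.items() if coverage[n] >= min_coverage}
    for n in set(extended) - set(kept):
        logger.info("filter_by_coverage dropped=%s coverage=%.3f", n, coverage[n])
    return kept


def rank_sum_test(set_scores: np.ndarray, bg_scores: np.ndarray,
                  exact_max: int = 10) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum of set vs background scores.

    Exact enumeration (via the exact Mann–Whitney null) when both groups
    have at most ``exact_max`` members and no ties straddle them; the
    tie-corrected normal approximation otherwise.  Returns (rank-sum of
    the set group, p-value).
    """
    x, y = np.asarray(set_scores, float), np.asarray(bg_scores, float)
    n1 = len(x)
    ties = len(np.unique(np.concatenate([x, y]))) < n1 + len(y)
    method = "exact" if (n1 <= exact_max and len(y) <= exact_max and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + n1 * (n1 + 1) / 2.0  # U -> rank sum of the set
    return w, float(res.pvalue)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, monotone, capped at 1."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich(weights: pd.Series, extended: dict[str, set[str]],
           direction: str = "all", coverage: dict[str, float] | None = None,
           alpha: float = 0.05) -> pd.DataFrame:
    """Rank-sum enrichment of factor weights over extended pathways.

    ``weights`` is a factor's signed weight per pooled feature id.  The
    tested score is the weight (positive direction), its negation
    (negative direction) or its absolute value (all); each pathway's
    features are compared against all remaining features and p-values are
    BH-adjusted across the tested pathways of this direction.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if direction == "positive":
        scores = weights
    elif direction == "negative":
        scores = -weights
    else:
        scores = weights.abs()
    universe = set(weights.index)
    rows = []
    for name in sorted(extended):
        feats = extended[name] & universe
        if not feats:
            logger.info("enrich skipped=%s reason=empty_after_extension", name)
            continue
        bg = universe - feats
        if not bg:
            logger.info("enrich skipped=%s reason=no_background", name)
            continue
        stat, p = rank_sum_test(scores[sorted(feats)].to_numpy(),
                                scores[sorted(bg)].to_numpy())
        rows.append({
            "pathway_id": name, "direction": direction, "statistic": stat,
            "p_value": p, "n_features": len(feats),
            "coverage": coverage.get(name, np.nan) if coverage else np.nan,
        })
    result = pd.DataFrame(rows)
    if len(result):
        result["adj_p"] = adjust_bh(result["p_value"].to_numpy())
        result["significant"] = result["adj_p"] < alpha
        result = result.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return result
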