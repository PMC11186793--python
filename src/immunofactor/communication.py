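"""Prior-guided ligand–receptor–target communication scoring.

Candidate target genes are taken from the top of a factor's weight
ranking (restricted to one sign), paired with ligands whose prior
regulatory-potential score for that target clears a high quantile of the
potential matrix, gated on the receptor side (the ligand must have a
receptor reliably detected in the target gene's cell-type cluster), and
finally screened by Spearman correlation of ligand vs target expression
across samples — optionally with a one-timepoint lag where a patient's
ligand level at TPi is paired with the target level at TPi+1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gfa import FactorModelFit, rank_features
from .io import MultiViewDataset
from .preprocess import FilterCriteria

logger = logging.getLogger("immunofactor.communication")

#: receptor reliability: pct > 30 & n > 600, or pct > 10 & n > 1200
RECEPTOR_CRITERIA = FilterCriteria([(30.0, 600), (10.0, 1200)])

#: timepoint lag mapping used for lagged ligand -> target pairing
LAG_MAP = [("TP1", "TP2"), ("TP2", "TP3"), ("TP3", "TP4")]


@dataclass
class PriorNetwork:
    """Ligand–receptor edges plus a ligand x target regulatory-potential matrix."""

    lr_edges: set[tuple[str, str]]
    potential: pd.DataFrame  # ligands x targets, scores >= 0

    def __post_init__(self) -> None:
        if (self.potential.to_numpy(float) < 0).any():
            raise ValueError("regulatory potential scores must be non-negative")
        edge_ligands = {l for l, _ in self.lr_edges}
        self.orphan_ligands = sorted(set(self.potential.index) - edge_ligands)

    def receptors_of(self, ligand: str) -> set[str]:
        return {r for l, r in self.lr_edges if l == ligand}


def read_prior_network(edges_path: str | Path, potential_path: str | Path) -> PriorNetwork:
    edges = pd.read_csv(edges_path, sep="\t")
    lr = set(zip(edges["ligand"].astype(str), edges["receptor"].astype(str)))
    pot_long = pd.read_csv(potential_path, sep="\t")
    potential = pot_long.pivot(index="ligand", columns="target", values="score").fillna(0.0)
    return PriorNetwork(lr_edges=lr, potential=potential)


def write_prior_network(network: PriorNetwork, edges_path: str | Path,
                        potential_path: str | Path) -> None:
    pd.DataFrame(sorted(network.lr_edges), columns=["ligand", "receptor"]).to_csv(
        edges_path, sep="\t", index=False)
    long = (network.potential.stack().rename("score").rename_axis(["ligand", "target"])
            .reset_index())
    long.to_csv(potential_path, sep="\t", index=False, float_format="%.17g")


def reliable_receptors(prevalence: pd.DataFrame,
                       criteria: FilterCriteria = RECEPTOR_CRITERIA) -> dict[int, set[str]]:
    """Per-cluster set of receptor genes passing either reliability pair."""
    out: dict[int, set[str]] = {}
    for c, sub in prevalence.groupby("cluster"):
        out[c] = {
            g for g, n, pct in zip(sub["gene"], sub["n_cells_expressing"],
                                   sub["pct_cells_expressing"])
            if criteria.keeps(pct, n)
        }
    return out


def select_targets(fit: FactorModelFit, factor: int, top_fraction: float = 0.01,
                   sign: str = "positive") -> list[str]:
    """Top-fraction features of a factor restricted to one weight sign."""
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    table, _ = rank_features(fit, factor, top_fraction)
    if sign == "positive":
        table = table[table["weight"] > 0]
    else:
        table = table[table["weight"] < 0]
    return list(table["feature"])


def candidate_pairs(network: PriorNetwork, targets: list[str],
                    potential_quantile: float = 0.97) -> tuple[pd.DataFrame, float]:
    """(ligand gene, target feature) pairs above the potential threshold.

    The threshold is the given quantile over *all* entries of the
    potential matrix (zeros included); a pair is kept when its score is at
    or above the threshold.
    """
    entries = network.potential.to_numpy(float).ravel()
    threshold = float(np.quantile(entries, potential_quantile))
    rows = []
    from .enrichment import feature_gene
    for tf in targets:
        gene = feature_gene(tf)
        if gene not in network.potential.columns:
            continue
        col = network.potential[gene]
        for ligand, score in col[col >= threshold].items():
            rows.append({"ligand": ligand, "target_feature": tf,
                         "regulatory_potential": float(score)})
    return pd.DataFrame(rows, columns=["ligand", "target_feature",
                                       "regulatory_potential"]), threshold


def _feature_views(dataset: MultiViewDataset, gene: str) -> list[str]:
    """All view::gene feature ids of the dataset carrying this gene symbol."""
    hits = []
    for name, v in dataset.views.items():
        if gene in set(v.feature_ids):
            hits.append(f"{name}::{gene}")
    return hits


def _series(dataset: MultiViewDataset, feature_id: str) -> pd.Series:
    view, gene = feature_id.split("::", 1)
    v = dataset.views[view]
    s = v.values[gene]
    if v.mask is not None:
        s = s[v.mask]
    return s.dropna()


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation with average ranks (ties handled)."""
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlate_pairs(dataset: MultiViewDataset, pairs: pd.DataFrame,
                    reliable: dict[int, set[str]], network: PriorNetwork,
                    min_abs_rho: float = 0.4, lag: int = 0,
                    min_pairs: int = 5) -> pd.DataFrame:
    """Spearman-screened ligand–target results with receptor gating.

    For ``lag=0`` the two features are correlated across the samples
    present in both; for ``lag=1`` each ACS patient contributes the pairs
    TP1→TP2, TP2→TP3 and TP3→TP4 (ligand at the earlier, target at the
    later timepoint).  A result is kept when |rho| clears ``min_abs_rho``,
    the ligand and target live in different views, and — for cluster-view
    targets — at least one receptor of the ligand is reliably detected in
    the target cluster.  Pairs with fewer than ``min_pairs`` usable
    observations are dropped with a log entry.
    """
    if lag not in (0, 1):
        raise ValueError("lag must be 0 or 1")
    meta = dataset.meta.set_index("sample_id")
    results = []
    for _, row in pairs.iterrows():
        ligand_gene, target_feature = row["ligand"], row["target_feature"]
        t_view = target_feature.split("::", 1)[0]
        if t_view.startswith("cluster"):
            cluster = int(t_view.split("_", 1)[1])
            receptors = network.receptors_of(ligand_gene)
            if not (receptors & reliable.get(cluster, set())):
                continue
        target_vals = _series(dataset, target_feature)
        for ligand_feature in _feature_views(dataset, ligand_gene):
            l_view = ligand_feature.split("::", 1)[0]
            if l_view == t_view:
                continue
            ligand_vals = _series(dataset, ligand_feature)
            if lag == 0:
                common = ligand_vals.index.intersection(target_vals.index)
                x = ligand_vals[common].to_numpy()
                y = target_vals[common].to_numpy()
            else:
                x_list, y_list = [], []
                lmeta = meta.loc[meta.index.intersection(ligand_vals.index)]
                tmeta = meta.loc[meta.index.intersection(target_vals.index)]
                for patient, sub in lmeta.groupby("patient_id"):
                    tp_to_sample_l = dict(zip(sub["timepoint"], sub.index))
                    tsub = tmeta[tmeta["patient_id"] == patient]
                    tp_to_sample_t = dict(zip(tsub["timepoint"], tsub.index))
                    for tp_l, tp_t in LAG_MAP:
                        if tp_l in tp_to_sample_l and tp_t in tp_to_sample_t:
                            x_list.append(ligand_vals[tp_to_sample_l[tp_l]])
                            y_list.append(target_vals[tp_to_sample_t[tp_t]])
                x, y = np.asarray(x_list), np.asarray(y_list)
            if len(x) < min_pairs:
                logger.info("correlate_pairs dropped ligand=%s target=%s n=%d reason=too_few",
                            ligand_feature, target_feature, len(x))
                continue
            rho = spearman(x, y)
            if np.isfinite(rho) and abs(rho) >= min_abs_rho:
                results.append({
                    "ligand_feature": ligand_feature,
                    "target_feature": target_feature,
                    "spearman_rho": rho, "n_pairs": len(x),
                    "regulatory_potential": row["regulatory_potential"],
                    "lagged": bool(lag),
                })
    return pd.DataFrame(results, columns=["ligand_feature", "target_feature",
                                          "spearman_rho", "n_pairs",
                                          "regulatory_potential", "lagged"])


def lagged_sample_pairs(meta: pd.DataFrame, patient_id: str) -> list[tuple[str, str]]:
    """The (ligand sample, target sample) id pairs the lag mapping yields."""
    sub = meta[meta["patient_id"] == patient_id]
    tp_to_sample = dict(zip(sub["timepoint"], sub["sample_id"]))
    return [(tp_to_sample[a], tp_to_sample[b]) for a, b in LAG_MAP
            if a in tp_to_sample and b in tp_to_sample]
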