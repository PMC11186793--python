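"""View-specific harmonization: pseudobulk, filters, normalizations.

Each modality gets the treatment appropriate to its measurement process
before everything is put on a common scale with a rank-based inverse
normal transform:

* single-cell counts are aggregated to per-cluster pseudobulk (mean count
  over a sample's cells in the cluster), depth-corrected to equal row
  totals, prevalence-filtered, log-transformed and quantile normalized;
* multiplex cytokines keep their out-of-range (OOR) token through parsing,
  are screened for a minimum fraction of valid measurements, then OOR is
  set to 0 and values are log1p-transformed;
* bulk neutrophil counts pass expression/coverage filters, equal-total
  scaling, log, a variance-quantile filter and quantile normalization;
* plasma proteomics (already log scale) is validity-filtered, median
  centered, and left-censored missing values are imputed from a
  downshifted Gaussian;
* clinical markers are log1p-transformed;
* cluster abundances go through a centered log-ratio (CLR) transform.

Every filter decision is recorded on a structured log so a run can be
audited rule by rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .io import MultiViewDataset, ViewMatrix

logger = logging.getLogger("immunofactor.preprocess")


# ---------------------------------------------------------------------------
# cell-level containers


@dataclass
class CellMatrix:
    """Cell x gene counts with per-cell sample and cluster labels."""

    counts: np.ndarray | sparse.spmatrix  # cells x genes, non-negative
    genes: list[str]
    cell_to_sample: np.ndarray  # str array, len = n_cells
    cell_to_cluster: np.ndarray  # int array, len = n_cells

    def __post_init__(self) -> None:
        n = self.counts.shape[0]
        if len(self.cell_to_sample) != n or len(self.cell_to_cluster) != n:
            raise ValueError("cell label arrays must match the count-matrix rows")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)


@dataclass
class FilterCriteria:
    """OR-combination of (min_pct, min_n) AND-pairs, strict inequalities.

    A gene survives iff for at least one pair both ``pct > min_pct`` and
    ``n > min_n`` hold, where pct is the percentage of the cluster's cells
    expressing the gene and n the absolute number.
    """

    pairs: list[tuple[float, int]]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("FilterCriteria needs at least one (min_pct, min_n) pair")

    def keeps(self, pct: float, n: int) -> bool:
        return any(pct > mp and n > mn for mp, mn in self.pairs)


#: discovery-cohort gene filter: pct > 50 & n > 1200, or pct > 40 & n > 3000
MUNICH_GENE_FILTER = FilterCriteria([(50.0, 1200), (40.0, 3000)])
#: validation-cohort variant with relaxed thresholds for shallower data
GRONINGEN_GENE_FILTER = FilterCriteria([(30.0, 1000), (20.0, 2500)])


# ---------------------------------------------------------------------------
# pseudobulk


def pseudobulk(cells: CellMatrix, min_cells: int = 1) -> dict[str, ViewMatrix]:
    """Aggregate cells to per-cluster sample x gene pseudobulk views.

    The entry for (sample, gene) in cluster c is the mean raw count over
    the sample's cells in c; afterwards each sample row is rescaled so all
    rows of the cluster view share the same total (the mean of the raw row
    totals), correcting for sequencing-depth differences.  (sample,
    cluster) pairs with no cells are left absent, not zero-filled.
    """
    X = cells.dense()
    samples = pd.unique(cells.cell_to_sample)
    clusters = np.unique(cells.cell_to_cluster)
    views: dict[str, ViewMatrix] = {}
    for c in clusters:
        rows, index = [], []
        in_c = cells.cell_to_cluster == c
        for s in samples:
            sel = in_c & (cells.cell_to_sample == s)
            if sel.sum() >= min_cells:
                rows.append(X[sel].mean(axis=0))
                index.append(s)
        if not rows:
            continue
        df = pd.DataFrame(np.vstack(rows), index=index, columns=cells.genes)
        df = equal_total_scaling(df)
        views[f"cluster_{c}"] = ViewMatrix(f"cluster_{c}", df)
    return views


def equal_total_scaling(df: pd.DataFrame) -> pd.DataFrame:
    """Rescale each row to the common target total (mean of row totals)."""
    totals = df.sum(axis=1)
    target = float(totals.mean())
    factors = target / totals.replace(0, np.nan)
    return df.mul(factors, axis=0)


def compute_prevalence(cells: CellMatrix) -> pd.DataFrame:
    """Per (cluster, gene): number and percentage of expressing cells.

    "Expressing" means raw count > 0; percentages pool the cluster's cells
    over all samples.
    """
    X = cells.dense() > 0
    records = []
    for c in np.unique(cells.cell_to_cluster):
        sel = cells.cell_to_cluster == c
        total = int(sel.sum())
        n_expr = X[sel].sum(axis=0)
        for g, n in zip(cells.genes, n_expr):
            records.append((c, g, int(n), 100.0 * n / total))
    return pd.DataFrame(records,
                        columns=["cluster", "gene", "n_cells_expressing",
                                 "pct_cells_expressing"])


def filter_genes(prevalence: pd.DataFrame,
                 criteria: FilterCriteria) -> dict[int, list[str]]:
    """Retained gene list per cluster under the OR-of-AND-pairs rule."""
    kept: dict[int, list[str]] = {}
    for c, sub in prevalence.groupby("cluster"):
        keep = [
            g for g, n, pct in zip(sub["gene"], sub["n_cells_expressing"],
                                   sub["pct_cells_expressing"])
            if criteria.keeps(pct, n)
        ]
        dropped = len(sub) - len(keep)
        logger.info("filter_genes cluster=%s kept=%d dropped=%d rule=%s",
                    c, len(keep), dropped, criteria.pairs)
        kept[c] = keep
    return kept


# ---------------------------------------------------------------------------
# normalizations


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Across-sample quantile normalization (rows = samples).

    Each sample's sorted values are replaced by the mean of the order
    statistics across samples; tied values share the mean of the reference
    values their ranks span, so the map is well defined under ties.
    """
    X = df.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("quantile_normalize expects complete rows (mask absent samples instead)")
    ref = np.sort(X, axis=1).mean(axis=0)
    csum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        rmin = stats.rankdata(X[i], method="min").astype(int)
        rmax = stats.rankdata(X[i], method="max").astype(int)
        out[i] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_pseudobulk(view: ViewMatrix) -> ViewMatrix:
    """log1p then across-sample quantile normalization of a filtered view."""
    present = view.values.dropna(how="all")
    norm = quantile_normalize(np.log1p(present))
    values = norm.reindex(view.values.index)
    return ViewMatrix(view.view_name, values, mask=view.mask)


def preprocess_cytokines(view: ViewMatrix, min_valid_fraction: float = 0.2) -> ViewMatrix:
    """Cytokine harmonization: validity screen, OOR -> 0, log1p.

    An entry is *valid* when it is neither missing nor OOR.  Cytokines with
    a valid fraction below ``min_valid_fraction`` (over samples present in
    the view) are excluded; the screen runs before the OOR substitution so
    out-of-range calls cannot rescue a mostly-unmeasured analyte.
    """
    present = view.values.index[view.values.notna().any(axis=1) | view.oor.any(axis=1)]
    vals = view.values.loc[present]
    oor = view.oor.loc[present]
    valid_frac = (vals.notna() & ~oor).mean(axis=0)
    keep = valid_frac[valid_frac >= min_valid_fraction].index
    for col in vals.columns.difference(keep):
        logger.info("preprocess_cytokines dropped=%s valid_fraction=%.3f rule=<%.2f",
                    col, valid_frac[col], min_valid_fraction)
    vals = vals[keep].where(~oor[keep], other=0.0)
    out = np.log1p(vals).reindex(view.values.index)
    return ViewMatrix(view.view_name, out, mask=view.mask)


def preprocess_neutrophils(view: ViewMatrix,
                           flag_prefixes: tuple[str, ...] = ("MT-", "RPL", "RPS"),
                           min_gene_sample_fraction: float = 0.8,
                           min_sample_gene_fraction: float = 0.9,
                           variance_quantile: float = 0.25) -> ViewMatrix:
    """Bulk neutrophil harmonization, steps applied in the stated order.

    Drop flagged (mitochondrial/ribosomal) genes; keep genes expressed in
    at least 80% of samples; keep samples with reads in at least 90% of the
    remaining genes; equal-total scaling; log1p; drop genes whose variance
    lies strictly below the 25% quantile of the variance distribution
    (linear-interpolation quantile, ties at the threshold kept); quantile
    normalization.
    """
    df = view.values.dropna(how="all")
    flagged = [g for g in df.columns if any(g.startswith(p) for p in flag_prefixes)]
    if flagged:
        logger.info("preprocess_neutrophils dropped_flagged=%d", len(flagged))
    df = df.drop(columns=flagged)

    expressed_frac = (df > 0).mean(axis=0)
    keep_genes = expressed_frac[expressed_frac >= min_gene_sample_fraction].index
    logger.info("preprocess_neutrophils gene_rule kept=%d dropped=%d",
                len(keep_genes), df.shape[1] - len(keep_genes))
    df = df[keep_genes]

    sample_cov = (df > 0).mean(axis=1)
    keep_samples = sample_cov[sample_cov >= min_sample_gene_fraction].index
    logger.info("preprocess_neutrophils sample_rule kept=%d dropped=%d",
                len(keep_samples), df.shape[0] - len(keep_samples))
    df = df.loc[keep_samples]
    if df.shape[0] == 0:
        raise ValueError("preprocess_neutrophils removed every sample")

    df = np.log1p(equal_total_scaling(df))

    variances = df.var(axis=0, ddof=1)
    threshold = float(np.quantile(variances.to_numpy(), variance_quantile))
    keep = variances[variances >= threshold].index
    logger.info("preprocess_neutrophils variance_rule threshold=%.6g kept=%d dropped=%d",
                threshold, len(keep), df.shape[1] - len(keep))
    df = quantile_normalize(df[keep])
    values = df.reindex(view.values.index)
    return ViewMatrix(view.view_name, values, mask=view.mask)


def preprocess_proteomics(view: ViewMatrix, min_valid: float = 0.8,
                          downshift: float = 1.8, width: float = 0.3,
                          seed: int = 0) -> ViewMatrix:
    """Proteomics validity filter, median centering, downshift imputation.

    Proteins (then samples) with fewer than ``min_valid`` valid values are
    removed; each protein is centered on its observed median; remaining
    missing entries are drawn from Normal(mu_p - downshift * sigma_p,
    (width * sigma_p)^2) with mu_p, sigma_p the protein's observed mean and
    SD — the standard treatment for left-censored, intensity-dependent
    dropout in label-free proteomics.  Deterministic given ``seed``.
    """
    df = view.values.dropna(how="all").copy()

    prot_valid = df.notna().mean(axis=0)
    keep_p = prot_valid[prot_valid >= min_valid].index
    for col in df.columns.difference(keep_p):
        logger.info("preprocess_proteomics dropped_protein=%s valid=%.3f", col, prot_valid[col])
    df = df[keep_p]
    samp_valid = df.notna().mean(axis=1)
    keep_s = samp_valid[samp_valid >= min_valid].index
    logger.info("preprocess_proteomics sample_rule kept=%d dropped=%d",
                len(keep_s), df.shape[0] - len(keep_s))
    df = df.loc[keep_s]

    df = df - df.median(axis=0, skipna=True)

    rng = np.random.default_rng(seed)
    for col in df.columns:
        col_vals = df[col]
        missing = col_vals.isna()
        if not missing.any():
            continue
        obs = col_vals.dropna()
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            draws = np.full(int(missing.sum()), mu - downshift * 0.0)
        else:
            draws = rng.normal(mu - downshift * sd, width * sd, size=int(missing.sum()))
        df.loc[missing, col] = draws
    values = df.reindex(view.values.index)
    return ViewMatrix(view.view_name, values, mask=view.mask)


def preprocess_clinical(view: ViewMatrix) -> ViewMatrix:
    """log1p the clinical markers; negative inputs are a hard error."""
    df = view.values
    neg = df < 0
    if neg.any().any():
        col = neg.any(axis=0).idxmax()
        row = neg[col].idxmax()
        raise ValueError(f"negative clinical value at row '{row}', column '{col}'")
    return ViewMatrix(view.view_name, np.log1p(df), mask=view.mask)


def inverse_normal_transform_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Feature-wise rank inverse normal transform, r/(n+1) offset.

    Per feature, observed values are mapped to standard-normal quantiles
    Phi^-1(r / (n + 1)) with average ranks for ties; missing entries are
    left untouched; a constant feature maps to all zeros.
    """
    out = df.copy().astype(float)
    for col in df.columns:
        obs = df[col].dropna()
        n = len(obs)
        if n == 0:
            continue
        if obs.nunique() == 1:
            out.loc[obs.index, col] = 0.0
            continue
        ranks = stats.rankdata(obs.to_numpy(), method="average")
        out.loc[obs.index, col] = stats.norm.ppf(ranks / (n + 1))
    return out


def inverse_normal_transform(dataset: MultiViewDataset) -> MultiViewDataset:
    """Apply the rank inverse normal transform to every view of a dataset."""
    views = {
        name: ViewMatrix(name, inverse_normal_transform_frame(v.values),
                         mask=v.mask)
        for name, v in dataset.views.items()
    }
    return MultiViewDataset(views=views, meta=dataset.meta)


# ---------------------------------------------------------------------------
# compositional analysis


def clr(proportions: np.ndarray) -> np.ndarray:
    """Centered log-ratio: log p_i - mean_j log p_j, rowwise for 2-D input."""
    p = np.asarray(proportions, float)
    logp = np.log(p)
    return logp - logp.mean(axis=-1, keepdims=True)


def clr_composition(cells: CellMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Sample x cluster CLR-transformed cell-type composition.

    Cluster cell counts per sample get a pseudocount (so empty clusters do
    not produce -inf), are converted to proportions and CLR-transformed;
    each output row sums to zero by construction.
    """
    tab = pd.crosstab(pd.Series(cells.cell_to_sample, name="sample"),
                      pd.Series(cells.cell_to_cluster, name="cluster"))
    counts = tab.to_numpy(float) + pseudocount
    props = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(clr(props), index=tab.index,
                        columns=[f"cluster_{c}" for c in tab.columns])
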