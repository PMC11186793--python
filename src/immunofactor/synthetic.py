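"""Synthetic longitudinal multiomic cohorts with known latent structure.

The generator emulates the design of a two-arm longitudinal immune study:
acute-event patients (``sterile_ACS``) sampled at four in-hospital
timepoints TP1–TP4, and two control arms (``CCS``, ``non_CCS``) sampled
once at TP0.  A K-factor linear latent structure is shared across six
views — two single-cell cluster pseudobulk panels, cytokines, plasma
proteomics, bulk neutrophil expression and clinical markers — with a
per-(view, factor) activity pattern so some pairs carry no signal at all
(the ground truth for variance-decomposition checks).

Two factors have designed roles:

* the *trajectory* factor follows a rise-then-decay profile over TP1→TP4
  in acute patients and is near zero in controls;
* the *outcome* factor is shifted at TP1 for poor-outcome patients by
  ``outcome_effect`` (in units of the factor's unit SD).

Real-data artifacts are reproduced on purpose: per-view missing samples,
out-of-range ("OOR") tokens in the cytokine table, left-censored
(intensity-dependent) missingness in proteomics, negative-binomial
overdispersion and per-cell library-size variation in the single-cell
counts, and timepoint-dependent cluster abundances to exercise the
compositional (CLR) analysis.  Everything is deterministic given the
config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .communication import PriorNetwork, write_prior_network
from .io import ViewMatrix, write_view_table
from .preprocess import CellMatrix

ACS_TIMEPOINTS = ("TP1", "TP2", "TP3", "TP4")
CONTROL_TIMEPOINT = "TP0"

#: rise-then-decay profile of the trajectory factor over TP1..TP4, scaled so
#: the factor's scores have ~unit SD across the default cohort (uniform
#: per-factor signal scale, hence a uniform per-factor SNR)
TRAJECTORY_PROFILE = {"TP1": 1.3, "TP2": 2.6, "TP3": 1.45, "TP4": 0.5}

#: timepoint multipliers on cluster 0's Dirichlet concentration
ABUNDANCE_SHIFT = {"TP0": 1.0, "TP1": 1.5, "TP2": 1.2, "TP3": 0.9, "TP4": 0.6}

BULK_VIEWS = ("cytokines", "proteomics", "neutrophils", "clinical")
CLINICAL_MARKERS = ("CK", "CKMB", "TROPT", "CRP")


@dataclass
class GeneratorConfig:
    """Study-design knobs of the synthetic cohort.

    Defaults encode the reference desk-scale cohort: 3 groups x 8
    patients, 4 acute timepoints, 6 views, 4 true factors, a
    signal-to-noise ratio of 2 on the bulk views (unit signal SD vs
    ``noise_sd`` = 0.5) and an outcome shift of 1.8 factor SD at TP1 —
    the effect size a factor with strong early prognostic value implies.
    """

    n_patients_per_group: int = 8
    n_factors_true: int = 4
    n_clusters: int = 2
    genes_per_cluster: int = 60
    cells_per_sample: int = 400
    n_cytokines: int = 30
    n_proteins: int = 60
    n_neutrophil_genes: int = 50
    n_clinical: int = 4
    noise_sd: float = 0.5
    trajectory_factor_index: int = 0
    outcome_factor_index: int = 1
    outcome_effect: float = 1.8
    missing_view_rate: float = 0.1
    oor_rate: float = 0.05
    protein_missing_rate: float = 0.15
    nb_dispersion: float = 0.1
    library_size_sd: float = 0.3
    #: log-fold scale of factor effects on single-cell expression; keeps the
    #: strongest planted genes within a few-fold dynamic range so depth
    #: normalization is not dominated by single outlier genes
    sc_effect_scale: float = 0.5
    n_planted_pairs: int = 3
    noise_free: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(n_patients_per_group=self.n_patients_per_group,
                      n_factors_true=self.n_factors_true,
                      n_clusters=self.n_clusters,
                      genes_per_cluster=self.genes_per_cluster,
                      cells_per_sample=self.cells_per_sample,
                      n_cytokines=self.n_cytokines, n_proteins=self.n_proteins,
                      n_neutrophil_genes=self.n_neutrophil_genes,
                      n_clinical=self.n_clinical)
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        for name in ("missing_view_rate", "oor_rate", "protein_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.noise_sd <= 0 and not self.noise_free:
            raise ValueError("noise_sd must be positive (or set noise_free)")
        for name in ("trajectory_factor_index", "outcome_factor_index"):
            if not 0 <= getattr(self, name) < self.n_factors_true:
                raise ValueError(f"{name} must be < n_factors_true")

    @property
    def view_names(self) -> list[str]:
        return [f"cluster_{c}" for c in range((self.n_clusters))] + list(BULK_VIEWS)


@dataclass
class CohortTruth:
    """Generator ground truth used by recovery tests."""

    Z_true: pd.DataFrame  # samples x K
    W_true: dict[str, pd.DataFrame]  # view -> features x K
    outcome_labels: pd.Series  # per acute patient: good / poor
    planted_ligand_target_pairs: list[tuple[str, str]]  # (ligand gene, target feature)
    meta: pd.DataFrame
    baselines: dict[str, np.ndarray]
    activity: pd.DataFrame  # view x factor boolean signal pattern
    receptor_of_ligand: dict[str, str]
    cluster_base_props: np.ndarray

    def __post_init__(self) -> None:
        assert len(self.Z_true) == len(self.meta)
        feats = {f"{v}::{f}" for v, W in self.W_true.items() for f in W.index}
        for ligand, target in self.planted_ligand_target_pairs:
            assert target in feats, f"planted target {target} not generated"


@dataclass
class SyntheticCohort:
    """Generated raw data: cells, raw bulk view tables, sample metadata."""

    cells: CellMatrix
    views: dict[str, ViewMatrix]
    meta: pd.DataFrame
    network: PriorNetwork


# ---------------------------------------------------------------------------
# design helpers


def _make_meta(config: GeneratorConfig, rng: np.random.Generator
               ) -> tuple[pd.DataFrame, pd.Series]:
    rows = []
    n = config.n_patients_per_group
    acs_patients = [f"ACS{i:02d}" for i in range(n)]
    # balanced outcome split (within rounding), order randomized
    labels = np.array(["good"] * (n - n // 2) + ["poor"] * (n // 2))
    rng.shuffle(labels)
    outcome = pd.Series(labels, index=acs_patients, name="outcome")
    for p in acs_patients:
        if outcome[p] == "good":
            d_ef = float(rng.uniform(2.0, 15.0))
        else:
            d_ef = float(-rng.uniform(2.0, 15.0))
        for tp in ACS_TIMEPOINTS:
            rows.append((f"{p}_{tp}", p, tp, "sterile_ACS", d_ef, outcome[p]))
    for group, prefix in (("CCS", "CCS"), ("non_CCS", "NCC")):
        for i in range(n):
            p = f"{prefix}{i:02d}"
            rows.append((f"{p}_{CONTROL_TIMEPOINT}", p, CONTROL_TIMEPOINT,
                         group, np.nan, "unknown"))
    meta = pd.DataFrame(rows, columns=["sample_id", "patient_id", "timepoint",
                                       "group", "delta_EF", "outcome"])
    return meta, outcome


def _make_activity(config: GeneratorConfig) -> pd.DataFrame:
    views = config.view_names
    K = config.n_factors_true
    act = np.zeros((len(views), K), dtype=bool)
    for m in range(len(views)):
        for k in range(K):
            act[m, k] = (m + k) % 3 != 2
    df = pd.DataFrame(act, index=views, columns=range(K))
    tf, of = config.trajectory_factor_index, config.outcome_factor_index
    # trajectory factor: everywhere except proteomics; outcome factor:
    # clusters + cytokines + proteomics + clinical, silent in neutrophils
    for v in views:
        df.loc[v, tf] = v != "proteomics"
        df.loc[v, of] = v != "neutrophils"
    # the 4 clinical injury markers track only the acute trajectory and the
    # outcome axis — and a 4-feature view cannot support more factors anyway
    df.loc["clinical"] = False
    df.loc["clinical", [tf, of]] = True
    # guarantee every view and every factor has signal somewhere
    for v in views:
        if not df.loc[v].any():
            df.loc[v, tf] = True
    for k in range(K):
        if not df[k].any():
            df.loc[views[k % len(views)], k] = True
    return df


def _feature_names(config: GeneratorConfig) -> dict[str, list[str]]:
    names: dict[str, list[str]] = {}
    for c in range(config.n_clusters):
        genes = [f"G{c}_{j:03d}" for j in range(config.genes_per_cluster)]
        genes[-1] = f"R{c}A"  # designated receptor gene, high baseline
        names[f"cluster_{c}"] = genes
    cyt = [f"CY{j:03d}" for j in range(config.n_cytokines)]
    for i in range(min(config.n_planted_pairs, config.n_cytokines)):
        cyt[i] = f"LG{i}"  # planted ligand analytes
    names["cytokines"] = cyt
    names["proteomics"] = [f"P{j:03d}" for j in range(config.n_proteins)]
    # flagged MT/RP genes are appended at generation time, outside W
    names["neutrophils"] = [f"N{j:03d}" for j in range(config.n_neutrophil_genes)]
    clin = list(CLINICAL_MARKERS[: config.n_clinical])
    clin += [f"CL{j}" for j in range(len(clin), config.n_clinical)]
    names["clinical"] = clin
    return names


def _make_truth(config: GeneratorConfig, rng: np.random.Generator) -> CohortTruth:
    meta, outcome = _make_meta(config, rng)
    n_samples = len(meta)
    K = config.n_factors_true
    tf, of = config.trajectory_factor_index, config.outcome_factor_index

    Z = rng.normal(size=(n_samples, K))
    traj = np.array([
        TRAJECTORY_PROFILE.get(tp, 0.0) if grp == "sterile_ACS" else 0.0
        for tp, grp in zip(meta["timepoint"], meta["group"])
    ])
    Z[:, tf] = traj + rng.normal(scale=0.25, size=n_samples)
    is_poor_tp1 = (
        (meta["group"] == "sterile_ACS") & (meta["timepoint"] == "TP1")
        & (meta["patient_id"].map(outcome) == "poor")
    ).to_numpy()
    Z[is_poor_tp1, of] += config.outcome_effect

    activity = _make_activity(config)
    names = _feature_names(config)
    W: dict[str, pd.DataFrame] = {}
    baselines: dict[str, np.ndarray] = {}
    for view in config.view_names:
        feats = names[view]
        D = len(feats)
        act = activity.loc[view].to_numpy()
        Wv = rng.normal(size=(D, K)) * act
        # balance mass across the view's active factors so every planted
        # active (view, factor) pair is genuinely active, then give each
        # feature unit signal SD
        n_active = max(int(act.sum()), 1)
        mass = (Wv ** 2).sum(axis=0)
        scale = np.where(mass > 0, np.sqrt(D / (n_active * np.maximum(mass, 1e-12))), 0.0)
        Wv = Wv * scale
        # ordinary features load on factor mixtures: cap the dominant
        # factor's share of each row at 80% so only designated marker
        # features (planted below) are pure single-factor markers
        if n_active > 1:
            for f in range(D):
                row = Wv[f]
                nrm2 = float(row @ row)
                if nrm2 <= 0:
                    continue
                j = int(np.argmax(np.abs(row)))
                rest = nrm2 - row[j] ** 2
                if rest > 0 and row[j] ** 2 > 0.64 * nrm2:
                    row[j] = np.sign(row[j]) * np.sqrt(0.64 * rest / 0.36)
        norms = np.linalg.norm(Wv, axis=1, keepdims=True)
        Wv = np.where(norms > 0, Wv / np.maximum(norms, 1e-12), 0.0)
        W[view] = pd.DataFrame(Wv, index=feats, columns=range(K))
    baselines["cytokines"] = rng.normal(3.0, 0.3, size=config.n_cytokines)
    baselines["proteomics"] = rng.normal(20.0, 1.0, size=config.n_proteins)
    baselines["neutrophils"] = np.concatenate([
        rng.normal(np.log(100.0), 0.5, size=config.n_neutrophil_genes),
        rng.normal(np.log(60.0), 0.3, size=4),  # flagged MT/RP genes
    ])
    baselines["clinical"] = rng.normal(4.0, 0.3, size=config.n_clinical)
    for c in range(config.n_clusters):
        # baselines span ~2 orders of magnitude like real expression panels;
        # a wide spread also keeps within-sample ranks from saturating under
        # quantile normalization
        b = rng.normal(np.log(2.0), 0.9, size=config.genes_per_cluster)
        b[-1] = np.log(6.0)  # receptor gene reliably expressed
        baselines[f"cluster_{c}"] = b

    # planted ligand -> target pairs: pure, strong trajectory-factor markers
    planted: list[tuple[str, str]] = []
    receptor_of: dict[str, str] = {}
    e_tf = np.zeros(K)
    e_tf[tf] = 1.0
    for i in range(config.n_planted_pairs):
        ligand = f"LG{i}"
        if ligand not in names["cytokines"]:
            break
        c = i % config.n_clusters
        target_gene = names[f"cluster_{c}"][i % (config.genes_per_cluster - 1)]
        W["cytokines"].loc[ligand] = e_tf
        W[f"cluster_{c}"].loc[target_gene] = 1.2 * e_tf
        # a planted pair must reference measurable features: the target is
        # reliably expressed so prevalence filtering cannot remove it
        gi = list(W[f"cluster_{c}"].index).index(target_gene)
        baselines[f"cluster_{c}"][gi] = np.log(4.0)
        planted.append((ligand, f"cluster_{c}::{target_gene}"))
        receptor_of[ligand] = f"R{c}A"

    base_props = np.full(config.n_clusters, 1.0 / config.n_clusters)
    return CohortTruth(
        Z_true=pd.DataFrame(Z, index=meta["sample_id"], columns=range(K)),
        W_true=W, outcome_labels=outcome,
        planted_ligand_target_pairs=planted, meta=meta, baselines=baselines,
        activity=activity, receptor_of_ligand=receptor_of,
        cluster_base_props=base_props,
    )


# ---------------------------------------------------------------------------
# data generation


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_single_cell_counts(config: GeneratorConfig, truth: CohortTruth,
                                rng: np.random.Generator | None = None,
                                samples: list[str] | None = None) -> CellMatrix:
    """Draw the cell x gene count matrix from the planted latent structure.

    Per cell: cluster from the sample's Dirichlet cluster proportions
    (cluster 0's concentration is timepoint-modulated), then gene counts
    from a negative binomial whose log-mean is the cluster-panel baseline
    plus the cluster view's W·z for the sample, times a per-cell
    library-size factor.  Genes of foreign cluster panels leak at a low
    constant rate so prevalence filtering has real work to do.
    """
    rng = rng if rng is not None else np.random.default_rng([config.seed, 2])
    meta = truth.meta.set_index("sample_id")
    sample_ids = samples if samples is not None else list(meta.index)
    genes: list[str] = []
    panel_slices: dict[int, slice] = {}
    for c in range(config.n_clusters):
        panel_slices[c] = slice(len(genes), len(genes) + config.genes_per_cluster)
        genes.extend(truth.W_true[f"cluster_{c}"].index)
    G = len(genes)
    leak_mean = 0.02

    blocks, cell_samples, cell_clusters = [], [], []
    for s in sample_ids:
        tp = meta.loc[s, "timepoint"]
        conc = 40.0 * truth.cluster_base_props.copy()
        conc[0] *= ABUNDANCE_SHIFT.get(tp, 1.0)
        props = rng.dirichlet(conc)
        clusters = rng.choice(config.n_clusters, size=config.cells_per_sample, p=props)
        z = truth.Z_true.loc[s].to_numpy()
        if config.library_size_sd > 0:
            lib = rng.lognormal(0.0, config.library_size_sd, size=config.cells_per_sample)
        else:
            lib = np.ones(config.cells_per_sample)
        mean = np.full((config.cells_per_sample, G), leak_mean)
        for c in range(config.n_clusters):
            sel = clusters == c
            if not sel.any():
                continue
            logmu = truth.baselines[f"cluster_{c}"] + \
                config.sc_effect_scale * (truth.W_true[f"cluster_{c}"].to_numpy() @ z)
            mean[sel, panel_slices[c]] = np.exp(logmu)
        mean = mean * lib[:, None]
        if config.noise_free:
            counts = mean
        else:
            counts = _nb_draw(rng, mean, config.nb_dispersion)
        blocks.append(counts)
        cell_samples.extend([s] * config.cells_per_sample)
        cell_clusters.extend(clusters.tolist())
    X = np.vstack(blocks)
    return CellMatrix(counts=X, genes=genes,
                      cell_to_sample=np.array(cell_samples),
                      cell_to_cluster=np.array(cell_clusters, dtype=int))


def _bulk_latent(config: GeneratorConfig, truth: CohortTruth, view: str,
                 rng: np.random.Generator) -> pd.DataFrame:
    W = truth.W_true[view].to_numpy()
    Z = truth.Z_true.to_numpy()
    signal = Z @ W.T
    if not config.noise_free:
        signal = signal + rng.normal(scale=config.noise_sd, size=signal.shape)
    latent = truth.baselines[view][: signal.shape[1]] + signal
    return pd.DataFrame(latent, index=truth.Z_true.index,
                        columns=truth.W_true[view].index)


def _generate_cytokines(config, truth, rng) -> ViewMatrix:
    latent = _bulk_latent(config, truth, "cytokines", rng)
    raw = np.expm1(np.clip(latent, 0.0, None))
    oor = pd.DataFrame(rng.random(raw.shape) < config.oor_rate,
                       index=raw.index, columns=raw.columns)
    values = raw.where(~oor, other=np.nan)
    return ViewMatrix("cytokines", values, oor=oor)


def _generate_proteomics(config, truth, rng) -> ViewMatrix:
    latent = _bulk_latent(config, truth, "proteomics", rng)
    X = latent.to_numpy()
    if config.protein_missing_rate > 0:
        zs = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
        # left-censoring: missingness logistic in the within-protein z-score;
        # intercept calibrated by bisection to hit the requested overall rate
        lo, hi = -20.0, 20.0
        for _ in range(60):
            c = 0.5 * (lo + hi)
            if (1.0 / (1.0 + np.exp(-(c - 2.0 * zs)))).mean() > config.protein_missing_rate:
                hi = c
            else:
                lo = c
        p_miss = 1.0 / (1.0 + np.exp(-(0.5 * (lo + hi) - 2.0 * zs)))
        X = np.where(rng.random(X.shape) < p_miss, np.nan, X)
    return ViewMatrix("proteomics", pd.DataFrame(X, index=latent.index,
                                                 columns=latent.columns))


def _generate_neutrophils(config, truth, rng) -> ViewMatrix:
    W = truth.W_true["neutrophils"].to_numpy()
    Z = truth.Z_true.to_numpy()
    logmu = truth.baselines["neutrophils"][None, : W.shape[0]] + Z @ W.T
    flagged = truth.baselines["neutrophils"][W.shape[0]:]
    logmu = np.hstack([logmu, np.tile(flagged, (len(Z), 1))])
    lib = rng.lognormal(0.0, 0.2, size=(len(Z), 1))
    mean = np.exp(logmu) * lib
    counts = mean if config.noise_free else _nb_draw(rng, mean, config.nb_dispersion)
    cols = list(truth.W_true["neutrophils"].index) + ["MT-ND1", "MT-CO1", "RPL3", "RPS4"]
    return ViewMatrix("neutrophils",
                      pd.DataFrame(np.asarray(counts, float),
                                   index=truth.Z_true.index, columns=cols))


def _generate_clinical(config, truth, rng) -> ViewMatrix:
    latent = _bulk_latent(config, truth, "clinical", rng)
    raw = np.expm1(np.clip(latent, 0.0, None))
    return ViewMatrix("clinical", raw)


def generate_prior_network(config: GeneratorConfig, truth: CohortTruth,
                           rng: np.random.Generator | None = None) -> PriorNetwork:
    """Prior ligand–receptor edges and regulatory-potential matrix.

    Decoy potentials are i.i.d. uniform; planted ligand–target entries are
    set above the 97% quantile of the matrix, and each planted ligand gets
    an edge to a receptor reliably expressed in its target's cluster.
    """
    rng = rng if rng is not None else np.random.default_rng([config.seed, 3])
    ligands = list(truth.W_true["cytokines"].index)
    targets = [g for c in range(config.n_clusters)
               for g in truth.W_true[f"cluster_{c}"].index]
    potential = pd.DataFrame(rng.uniform(0.0, 1e-3, size=(len(ligands), len(targets))),
                             index=ligands, columns=targets)
    edges: set[tuple[str, str]] = set()
    receptors = [f"R{c}A" for c in range(config.n_clusters)]
    for lig in ligands:
        if lig not in truth.receptor_of_ligand and rng.random() < 0.3:
            edges.add((lig, receptors[int(rng.integers(config.n_clusters))]))
    high = 2.0 * float(np.quantile(potential.to_numpy().ravel(), 0.97))
    for ligand, target_feature in truth.planted_ligand_target_pairs:
        gene = target_feature.split("::", 1)[1]
        potential.loc[ligand, gene] = high * (1.0 + rng.random())
        edges.add((ligand, truth.receptor_of_ligand[ligand]))
    return PriorNetwork(lr_edges=edges, potential=potential)


def generate_cohort(config: GeneratorConfig,
                    shared_truth: CohortTruth | None = None
                    ) -> tuple[SyntheticCohort, CohortTruth]:
    """Generate one cohort (cells + raw bulk tables + metadata) and its truth.

    With ``shared_truth`` given, the weight matrices, baselines, activity
    pattern and planted pairs are reused while metadata, factor scores and
    all noise are redrawn — the setup for two cohorts measuring the same
    biology, as cross-cohort replication tests require.
    """
    rng_truth = np.random.default_rng([config.seed, 1])
    truth = _make_truth(config, rng_truth)
    if shared_truth is not None:
        truth = dataclasses.replace(
            truth,
            W_true=shared_truth.W_true,
            baselines=shared_truth.baselines,
            activity=shared_truth.activity,
            planted_ligand_target_pairs=shared_truth.planted_ligand_target_pairs,
            receptor_of_ligand=shared_truth.receptor_of_ligand,
            cluster_base_props=shared_truth.cluster_base_props,
        )

    rng_miss = np.random.default_rng([config.seed, 4])
    n = len(truth.meta)
    sample_ids = list(truth.meta["sample_id"])
    n_missing = int(np.floor(config.missing_view_rate * n))

    def _drop(ids: list[str]) -> list[str]:
        if n_missing == 0:
            return ids
        gone = set(rng_miss.choice(ids, size=n_missing, replace=False))
        return [s for s in ids if s not in gone]

    sc_samples = _drop(sample_ids)
    cells = generate_single_cell_counts(
        config, truth, np.random.default_rng([config.seed, 2]), samples=sc_samples)

    rng_bulk = np.random.default_rng([config.seed, 5])
    views: dict[str, ViewMatrix] = {}
    for name, gen in (("cytokines", _generate_cytokines),
                      ("proteomics", _generate_proteomics),
                      ("neutrophils", _generate_neutrophils),
                      ("clinical", _generate_clinical)):
        v = gen(config, truth, rng_bulk)
        keep = _drop(sample_ids)
        views[name] = ViewMatrix(name, v.values.loc[keep], oor=v.oor.loc[keep])

    network = generate_prior_network(config, truth,
                                     np.random.default_rng([config.seed, 3]))
    cohort = SyntheticCohort(cells=cells, views=views, meta=truth.meta,
                             network=network)
    return cohort, truth


def make_planted_pathways(truth: CohortTruth, factor: int, n_genes: int = 15,
                          n_decoys: int = 50, seed: int = 0) -> dict[str, set[str]]:
    """A gene-set collection with one truly factor-loaded pathway + decoys.

    The planted set holds the cluster-view genes with the largest absolute
    true weight on ``factor``; decoys are size-matched random draws from
    the same gene universe.
    """
    cluster_views = [v for v in truth.W_true if v.startswith("cluster")]
    loadings = pd.concat([truth.W_true[v][factor].abs() for v in cluster_views])
    loadings = loadings.groupby(level=0).max()
    planted = set(loadings.sort_values(ascending=False).index[:n_genes])
    universe = list(loadings.index)
    rng = np.random.default_rng([seed, 17])
    pathways = {"PLANTED": planted}
    for d in range(n_decoys):
        pathways[f"DECOY{d:03d}"] = set(rng.choice(universe, size=n_genes, replace=False))
    return pathways


# ---------------------------------------------------------------------------
# on-disk representation


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write cells (MTX + annotation TSV), bulk views, metadata and priors."""
    out = Path(out_dir)
    (out / "views").mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "cells.mtx"),
                 sparse.csr_matrix(np.asarray(cohort.cells.dense())))
    pd.DataFrame({
        "cell_id": [f"cell{i:06d}" for i in range(cohort.cells.n_cells)],
        "sample_id": cohort.cells.cell_to_sample,
        "cluster": cohort.cells.cell_to_cluster,
    }).to_csv(out / "cells.tsv", sep="\t", index=False)
    pd.Series(cohort.cells.genes, name="gene").to_csv(out / "genes.tsv",
                                                      sep="\t", index=False)
    for name, view in cohort.views.items():
        write_view_table(view, out / "views" / f"{name}.tsv")
    cohort.meta.to_csv(out / "meta.tsv", sep="\t", index=False)
    write_prior_network(cohort.network, out / "lr_edges.tsv", out / "potential.tsv")


def load_cohort(in_dir: str | Path) -> SyntheticCohort:
    from .communication import read_prior_network
    from .io import read_sample_meta, read_view_table

    src = Path(in_dir)
    counts = np.asarray(spio.mmread(str(src / "cells.mtx")).todense())
    ann = pd.read_csv(src / "cells.tsv", sep="\t", dtype={"sample_id": str})
    genes = pd.read_csv(src / "genes.tsv", sep="\t")["gene"].tolist()
    cells = CellMatrix(counts=counts, genes=genes,
                       cell_to_sample=ann["sample_id"].to_numpy(),
                       cell_to_cluster=ann["cluster"].to_numpy(int))
    views = {p.stem: read_view_table(p, p.stem)
             for p in sorted((src / "views").glob("*.tsv"))}
    meta = read_sample_meta(src / "meta.tsv")
    network = read_prior_network(src / "lr_edges.tsv", src / "potential.tsv")
    return SyntheticCohort(cells=cells, views=views, meta=meta, network=network)
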