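# Methods

## Study design emulated by the synthetic cohort

The generator reproduces the structure of a two-arm longitudinal immune
study of acute coronary syndrome (ACS): one patient group sampled at four
in-hospital timepoints (TP1 at catheterization through TP4 before
discharge) and two control arms (chronic coronary syndrome and
non-coronary controls) sampled once. A "sample" is one patient at one
timepoint, measured — with realistic per-view dropout — in six views: two
single-cell cluster pseudobulk panels, multiplex cytokines, plasma
proteomics (log intensities), bulk neutrophil counts and four clinical
injury markers (CK, CK-MB, troponin, CRP).

All views share a K-factor linear latent structure. Each view × factor
pair is either active or inactive by design (the ground truth for the
variance-decomposition checks); active weights are drawn at random, mass-
balanced across a view's active factors, and each feature's weight row is
normalized to unit signal SD. Two factors have designed roles:

* **trajectory factor** — per-timepoint profile (1.3, 2.6, 1.45, 0.5) over
  TP1..TP4 in ACS patients plus N(0, 0.25²) patient noise; N(0, 0.25²) in
  controls. The profile amplitude is chosen so the factor's marginal SD
  across the cohort is ≈ 1, i.e. the same signal scale as the other
  factors — without this, "active pair" would be ill-defined for the
  weakest view × factor combinations.
* **outcome factor** — standard normal, shifted by `outcome_effect`
  (default 1.8 SD) at TP1 for poor-outcome patients. 1.8 SD is the effect
  size implied by a factor with strong early prognostic value (an AUC
  around 0.9); outcome labels are assigned half good / half poor, with the
  ejection-fraction change drawn with the matching sign.

Ordinary features load on factor *mixtures*: the dominant factor's share
of each weight row is capped at 80%. Only the designated planted markers
(three cytokine ligands and their cluster target genes, plus the
reliably-expressed receptor genes) are pure single-factor features. This
is deliberate: after rank-based normalization a feature's effective weight
saturates at its correlation with the factor, so "the planted markers top
the ranking" is only a well-posed claim if decoys are genuinely mixed.

Realistic artifacts reproduced on purpose:

* negative-binomial counts (dispersion 0.1, variance μ + 0.1 μ²) with
  per-cell lognormal library-size factors (σ = 0.3);
* single-cell baselines spanning ~2 orders of magnitude (log-normal,
  σ = 0.9) — besides realism, a wide baseline spread keeps within-sample
  ranks from saturating under quantile normalization;
* factor effects on single-cell expression scaled to 0.5 log-units per
  factor SD, keeping the strongest genes within a few-fold dynamic range
  so depth normalization is not dominated by outlier genes;
* cluster proportions from a Dirichlet whose cluster-0 concentration is
  timepoint-modulated (1.5× at TP1 falling to 0.6× at TP4), the planted
  compositional shift for the CLR analysis;
* literal `OOR` tokens in the cytokine table (rate 0.05), left-censored
  proteomics missingness (overall rate 0.15; the missingness probability
  is logistic in the within-protein z-score with slope −2, intercept
  calibrated by bisection), and per-view missing samples (rate 0.1);
* flagged mitochondrial/ribosomal genes in the neutrophil table.

What the generator does **not** emulate: batch and chemistry effects,
doublets, ambient RNA, nonlinear factor interactions, informative (outcome-
dependent) missingness, and annotation disagreement between cohorts
(cross-cohort cluster matching is reduced to an explicit name-mapping
table). Passing tests therefore demonstrate the pipeline's correctness and
its behavior under linear latent structure with realistic noise and
missingness — not robustness to every artifact of real multiomic data.

## Harmonization rules

Applied per view, in this order, with every filter decision logged:

* **pseudobulk**: per (sample, cluster) the mean raw count over cells;
  rows rescaled to a common total (the mean of row totals); pairs with no
  cells stay absent. Gene retention per cluster requires
  pct-expressing > 50 and n-expressing > 1,200, OR > 40 and > 3,000
  (the validation-cohort preset relaxes these to 30/1,000 and 20/2,500);
  then log1p and across-sample quantile normalization.
* **cytokines**: analytes with valid (non-missing, non-OOR) measurements
  in fewer than 20% of the view's samples are removed *before* the OOR
  substitution; then OOR → 0 and log1p.
* **neutrophils**: drop flagged MT-/RPL/RPS genes → keep genes expressed
  in ≥ 80% of samples → keep samples with reads in ≥ 90% of remaining
  genes → equal-total scaling → log1p → drop genes with variance strictly
  below the 25% quantile (linear-interpolation quantile; ties at the
  threshold kept) → quantile normalization.
* **proteomics**: keep proteins, then samples, with ≥ 80% valid values;
  median-center each protein; impute each missing entry from
  N(μ_p − 1.8 σ_p, (0.3 σ_p)²) with μ_p, σ_p the protein's observed mean
  and SD. The 0.3 width is the common Perseus-style convention for
  left-censored label-free proteomics. Deterministic given the seed.
* **clinical**: log1p (shared with cytokines for zero-safety); negative
  inputs are a hard error.
* **inverse normal transform**: per feature, Φ⁻¹(r/(n+1)) with average
  ranks for ties; constant features map to 0; missing entries untouched.
* **CLR composition**: cluster counts + 0.5 pseudocount → proportions →
  log p − mean log p.

Quantile normalization uses the classic mean-of-order-statistics
reference; tied values share the mean of the reference values their ranks
span, computed exactly via min/max ranks and a cumulative sum.

## Factor model

MAP-EM for the Gaussian ARD group factor model (model equations in the
README). Numerical choices:

* deterministic initialization from the SVD of the concatenated data,
  each view scaled by 1/√D_m, absent entries at zero, singular-vector
  signs fixed; the `seed` argument exists for interface uniformity only;
* per-pattern posterior covariances (samples sharing an observed-view
  pattern share Σ), closed-form M-steps for W, τ, α;
* τ and α capped at 10⁸ — on noiseless data the likelihood diverges and
  the caps keep iterations finite; EM monotonicity holds up to the caps;
* the tracked objective is the negative log joint (exact marginal
  likelihood of the observed data plus the ARD prior on W), computable
  cheaply from the E-step quantities;
* convergence is judged on the objective's relative change over a
  50-iteration window (default tol 10⁻⁶): in the long shallow tail of the
  ARD rotation per-iteration changes are ~10⁻⁸ long before factors
  settle, so a per-iteration criterion stops too early;
* K may exceed a single view's feature count (a 4-marker clinical view
  inside a K = 20 model is a legitimate design) but not the sample count
  or the total feature count;
* factors are ordered by total explained sum of squares and signed so
  each factor's largest-|weight| feature is positive; variance fractions
  use uncentered sums of squares, valid because inputs are inverse-normal
  transformed.

Identifiability: factors are identified through their distinct view-
activity footprints (the ARD prior breaks rotational symmetry); two
factors with heavily overlapping footprints can land in a rotated local
optimum, which is why recovery criteria are stated as ≥ 9/10 seeds rather
than always.

## Downstream stages

* **Projection** uses the printed right-inverse formula on the jointly
  matched feature set; a condition-number guard at 10¹⁰ rejects
  degenerate matchings (ARD-pruned all-zero factors must be dropped
  before projecting — `active_factors` provides the index set). Targets
  must be preprocessed with the source recipe; the projector refuses
  matrices with missing entries.
* **Enrichment** extends symbol-keyed gene sets (GMT) to the pooled
  feature space (a gene hits once per view), removes pathways with < 20%
  gene coverage, and tests set vs background scores with the two-sided
  Wilcoxon rank-sum: exact enumeration when both groups have ≤ 10
  members and no ties, tie-corrected normal approximation otherwise;
  scores are the signed weights (positive direction), negated weights
  (negative) or absolute weights (joint mode — the absolute choice for
  the joint mode is an explicit design decision). BH adjustment is
  applied within each direction.
* **Communication** takes targets from the top ⌈fraction · D⌉ features
  restricted to one sign, ligand–target pairs at or above the 97%
  quantile of the full potential matrix (zeros included; inclusive at the
  boundary), requires a reliably measured receptor in cluster-view
  targets (pct > 30 ∩ n > 600, or pct > 10 ∩ n > 1,200), and keeps pairs
  with |Spearman ρ| ≥ 0.4 over ≥ 5 paired observations. The lagged screen
  maps each ACS patient's TP1→TP2, TP2→TP3 and TP3→TP4. Cytokine ligands
  face the receptor gate only for cluster-view targets.
* **Prediction**: outcome is the sign of the ejection-fraction change,
  with the two cohort rules for ΔEF = 0 (discovery: good; validation:
  poor) preserved verbatim rather than harmonized. ROC AUC is the
  normalized rank statistic. The lasso is an own glmnet-style
  implementation (outer IRLS quadratic approximation, cyclic coordinate
  descent with soft thresholding, active-set iteration, warm starts along
  a 100-point log-spaced path from λ_max down to 10⁻⁴ λ_max, path stop
  once 99% of the null deviance is explained); cross-validation folds are
  deterministic given the seed and stratified by class (a stabilizing
  choice at n ≈ 20; a flag restores unstratified folds), the selected
  penalty is the deviance-minimizing λ ("lambda.min") and the final model
  is refit on all data with coefficients reported on the original scale.
  The unpenalized logistic model uses IRLS (statsmodels GLM) and raises
  on separation.

## Problem sizes used by the tests and the acceptance script

Recovery-style properties run on the reference cohort (48 samples, ~230
features after filtering, K = 8 fit, 10 seeds); prediction properties use
24 patients per group (12 good vs 12 poor at TP1), 10 seeds for the
planted effect and the cross-cohort transfer (30-point lasso path,
λ-ratio 10⁻²) and 10–20 seeds for the null; the K-robustness check fits
K ∈ {5, 10, 15, 20} on one reference cohort. These sizes were chosen as
the smallest at which the recovery properties are statistically stable.

## Known limitations

* The factor model is Gaussian-likelihood only (no count or logit
  likelihoods) and omits feature-wise spike-and-slab sparsity; the
  quantities consumed downstream (Z, W, variance fractions, rankings,
  projections) are defined identically without it.
* No Gaussian-process smoothing across timepoints; time enters only
  through the planted trajectory.
* EM finds local optima; deterministic initialization trades global-
  optimum search for bit-reproducibility.
* The lagged communication screen has low power against instantaneous
  coupling (the only kind the generator plants) when the trajectory's
  lag-1 autocorrelation is negative, and the default screen reflects
  that honestly.
* Filter thresholds are tuned to cohort-scale cell counts; on miniature
  cohorts the defaults can legitimately empty a view (use the threshold
  overrides).
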