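# immunofactor

Multi-view factor analysis of longitudinal multiomic immune cohorts.

The package implements, end to end, the analysis workflow used to profile
the systemic immune response to an acute coronary event from blood drawn at
several timepoints: single-cell RNA-seq summarized to per-cell-type
pseudobulk, multiplex cytokines, plasma proteomics, bulk neutrophil
expression and clinical injury markers are harmonized onto a common scale,
integrated by a multi-view (group) factor model, and interrogated
downstream — variance decomposition, factor-weight pathway enrichment,
prior-guided ligand–target communication scoring, cross-cohort factor
projection and outcome prediction. Because the patient data such studies
rest on are access-restricted, the package ships a synthetic cohort
generator with known latent structure, so every stage is testable and every
reported number is recomputable from scratch.

## The model

Each sample *n* (one patient at one timepoint) is measured in *M* views.
The group factor model assumes a shared K-dimensional latent score vector
**z**ₙ:

```
y⁽ᵐ⁾ₙ = W⁽ᵐ⁾ zₙ + ε⁽ᵐ⁾,   ε⁽ᵐ⁾ ~ N(0, τₘ⁻¹ I),   zₙ ~ N(0, I_K)
```

with an automatic-relevance-determination (ARD) prior on each weight column,
`W⁽ᵐ⁾[:,k] ~ N(0, αₘₖ⁻¹ I)`, so factor–view pairs without signal are shrunk
to zero and the per-(factor, view) variance decomposition

```
R²ₘₖ = 1 − ‖Y⁽ᵐ⁾ − zₖ w⁽ᵐ⁾ₖᵀ‖² / ‖Y⁽ᵐ⁾‖²
```

cleanly separates active from inactive pairs. Estimation is EM with exact
per-sample posteriors over **z** (samples absent from a view contribute
nothing to that view), deterministic SVD initialization, factors ordered by
explained variance. A model fitted on one cohort transfers to another via
the right inverse of its weight matrix restricted to matched features:

```
Z_target = Y_target Wᵀ (W Wᵀ)⁻¹
```

## Worked example

The numbered scripts under `analysis/` run the whole study on the reference
synthetic cohort (3 patient groups × 8 patients, 4 acute timepoints, 6
views) and write their tables under `results/`. For instance:

```
$ python analysis/04_replicate_in_second_cohort.py
projected trajectory factor F2: |r| = 0.983 against the validation cohort's true scores
validation-cohort trajectory (per-timepoint mean): TP1=+1.01, TP2=+3.27, TP3=+1.56, TP4=-1.08

$ python analysis/07_predict_outcome.py
                  predictor      auc
                  factor_F1 0.944444
                clinical_CK 0.798611
              clinical_CKMB 0.861111
             clinical_TROPT 0.840278
               clinical_CRP 0.805556
lasso_top_features_transfer 0.805556
lasso kept 9/40 features at lambda.min = 0.01375; transfer AUC 0.806 on 24 held-out patients
```

The first run fits the factor model on a discovery cohort, projects an
independently generated validation cohort onto the same factors and shows
that the planted rise-then-decay disease-course factor replicates
(|r| = 0.98 against the validation cohort's true scores, with the TP2 peak
reproduced). The second shows the outcome factor at the first acute
timepoint discriminating good from poor recovery (AUC 0.94) better than any
single clinical marker, and a cross-validated lasso on the factor's top
features transferring to the held-out cohort at AUC 0.81.

The same stages are available as a CLI
(`immunofactor simulate | ingest | preprocess | fit | project | enrich |
communicate | predict | pipeline | report`); `immunofactor pipeline` runs
everything with a manifest of parameter and output hashes so a rerun with
the same seed reproduces all artifacts bit-identically.

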