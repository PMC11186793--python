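import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from immunofactor.gfa import fit_gfa
from immunofactor.io import ViewMatrix, align_samples
from immunofactor.pipeline import harmonize_cohort
from immunofactor.synthetic import GeneratorConfig, generate_cohort

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_dataset(Ys, view_names=None, sample_ids=None):
    """Assemble a MultiViewDataset from raw arrays (one sample universe)."""
    n = Ys[0].shape[0]
    ids = sample_ids or [f"P{i:03d}_TP1" for i in range(n)]
    meta = pd.DataFrame({
        "sample_id": ids,
        "patient_id": [s.rsplit("_", 1)[0] for s in ids],
        "timepoint": [s.rsplit("_", 1)[1] for s in ids],
        "group": "sterile_ACS",
    })
    views = []
    for m, Y in enumerate(Ys):
        name = view_names[m] if view_names else f"v{m}"
        cols = [f"{name}_g{j}" for j in range(Y.shape[1])]
        frame = pd.DataFrame(Y, index=ids, columns=cols)
        # all-NaN rows denote samples the view did not measure
        frame = frame.dropna(how="all")
        views.append(ViewMatrix(name, frame))
    return align_samples(views, meta)


def match_factor(fit, truth, dataset, true_factor):
    """Best-matching fitted factor index and its signed correlation."""
    ids = list(dataset.meta["sample_id"])
    zt = truth.Z_true.loc[ids, true_factor].to_numpy()
    with np.errstate(invalid="ignore"):
        corrs = np.array([np.corrcoef(fit.Z[:, k], zt)[0, 1] for k in range(fit.K)])
    corrs = np.nan_to_num(corrs)
    k = int(np.abs(corrs).argmax())
    return k, float(corrs[k])


@pytest.fixture(scope="session")
def fitted_cohorts():
    """Ten default-condition synthetic cohorts with harmonized data and fits.

    Shared across the recovery-style checks so the expensive part (ten
    generator + EM runs) happens once per session.
    """
    out = []
    for seed in range(10):
        config = GeneratorConfig(seed=seed)
        cohort, truth = generate_cohort(config)
        dataset, prevalence = harmonize_cohort(cohort, seed=seed)
        fit = fit_gfa(dataset, K=8, max_iter=30_000, seed=seed)
        out.append({"config": config, "cohort": cohort, "truth": truth,
                    "dataset": dataset, "prevalence": prevalence, "fit": fit})
    return out


@pytest.fixture()
def small_cohort():
    config = GeneratorConfig(seed=11, n_patients_per_group=4, cells_per_sample=60,
                             genes_per_cluster=20, n_cytokines=8, n_proteins=15,
                             n_neutrophil_genes=12)
    cohort, truth = generate_cohort(config)
    return config, cohort, truth
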