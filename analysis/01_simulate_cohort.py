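"""Generate the reference synthetic cohort and summarize its design.

Writes the full cohort (cells as MTX, bulk views, metadata, prior network)
under scratch/cohort for the downstream steps, and small summary tables
under results/: the sample design and the CLR-transformed cell-type
composition per timepoint (the compositional readout of the planted
cluster-0 abundance shift).
"""

from pathlib import Path

import pandas as pd

from immunofactor.preprocess import clr_composition
from immunofactor.synthetic import GeneratorConfig, generate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 0


def main() -> None:
    config = GeneratorConfig(seed=SEED)
    cohort, truth = generate_cohort(config)
    write_cohort(cohort, ROOT / "scratch" / "cohort")

    (ROOT / "results").mkdir(exist_ok=True)
    design = (cohort.meta.groupby(["group", "timepoint"], observed=True)
              .size().rename("n_samples").reset_index())
    design.to_csv(ROOT / "results" / "cohort_design.tsv", sep="\t", index=False)

    comp = clr_composition(cohort.cells)
    comp = comp.join(cohort.meta.set_index("sample_id")[["group", "timepoint"]])
    by_tp = comp.groupby(["group", "timepoint"], observed=True).mean(numeric_only=True)
    by_tp.to_csv(ROOT / "results" / "clr_composition_by_timepoint.tsv", sep="\t")

    print(f"cohort: {len(cohort.meta)} samples, {cohort.cells.n_cells} cells, "
          f"{len(cohort.views) + config.n_clusters} views")
    acs = by_tp.loc["sterile_ACS", "cluster_0"]
    print("CLR(cluster_0) along the acute course:",
          ", ".join(f"{tp}={v:+.2f}" for tp, v in acs.items()),
          "- the planted early-monocyte-like abundance peak declines over time")


if __name__ == "__main__":
    main()
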