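"""Synthetic cohort generator: determinism, planted structure, artifacts."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunofactor.preprocess import pseudobulk
from immunofactor.synthetic import (GeneratorConfig, generate_cohort,
                                    generate_prior_network,
                                    generate_single_cell_counts, load_cohort,
                                    write_cohort)


SMALL = dict(n_patients_per_group=4, cells_per_sample=60, genes_per_cluster=20,
             n_cytokines=8, n_proteins=15, n_neutrophil_genes=12)


class TestConfigValidation:
    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError, match="n_clusters"):
            GeneratorConfig(n_clusters=0)

    def test_fractions_in_unit_interval(self):
        with pytest.raises(ValueError, match="oor_rate"):
            GeneratorConfig(oor_rate=1.0)

    def test_factor_indices_bounded(self):
        with pytest.raises(ValueError, match="outcome_factor_index"):
            GeneratorConfig(n_factors_true=2, outcome_factor_index=2)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for d in ("a", "b"):
            cohort, _ = generate_cohort(GeneratorConfig(seed=1, **SMALL))
            write_cohort(cohort, tmp_path / d)
        files = [p.relative_to(tmp_path / "a")
                 for p in (tmp_path / "a").rglob("*") if p.is_file()]
        assert files
        for f in files:
            assert filecmp.cmp(tmp_path / "a" / f, tmp_path / "b" / f,
                               shallow=False), f

    def test_different_seed_differs(self):
        c1, _ = generate_cohort(GeneratorConfig(seed=1, **SMALL))
        c2, _ = generate_cohort(GeneratorConfig(seed=2, **SMALL))
        assert not np.array_equal(c1.cells.dense(), c2.cells.dense())

    def test_cohort_round_trips_through_disk(self, tmp_path):
        cohort, _ = generate_cohort(GeneratorConfig(seed=3, **SMALL))
        write_cohort(cohort, tmp_path / "c")
        back = load_cohort(tmp_path / "c")
        assert np.array_equal(back.cells.dense(), cohort.cells.dense())
        assert back.network.lr_edges == cohort.network.lr_edges
        pd.testing.assert_frame_equal(
            back.views["cytokines"].oor, cohort.views["cytokines"].oor)


class TestDesign:
    def test_one_sample_per_patient_timepoint(self):
        cohort, _ = generate_cohort(GeneratorConfig(seed=0, **SMALL))
        meta = cohort.meta
        assert not meta.duplicated(["patient_id", "timepoint"]).any()
        acs = meta[meta["group"] == "sterile_ACS"]
        assert set(acs["timepoint"]) == {"TP1", "TP2", "TP3", "TP4"}
        assert (meta[meta["group"] != "sterile_ACS"]["timepoint"] == "TP0").all()

    def test_outcome_balance_within_rounding(self):
        _, truth = generate_cohort(GeneratorConfig(seed=0, **SMALL))
        counts = truth.outcome_labels.value_counts()
        assert abs(counts.get("good", 0) - counts.get("poor", 0)) <= 1

    def test_trajectory_rises_then_decays_and_controls_near_zero(self):
        _, truth = generate_cohort(GeneratorConfig(seed=0, **SMALL))
        meta = truth.meta.set_index("sample_id")
        z = truth.Z_true[0]
        tp_means = z.groupby(meta["timepoint"]).mean()
        assert tp_means["TP2"] > tp_means["TP1"] > tp_means["TP4"]
        controls = z[meta["group"] != "sterile_ACS"]
        assert abs(controls.mean()) < 0.5

    def test_outcome_shift_at_tp1(self):
        effect = 1.8
        shifts = []
        for seed in range(5):
            _, truth = generate_cohort(GeneratorConfig(seed=seed, **SMALL,
                                                       outcome_effect=effect))
            meta = truth.meta.set_index("sample_id")
            z = truth.Z_true[1]
            tp1 = meta["timepoint"] == "TP1"
            poor = meta["patient_id"].map(truth.outcome_labels) == "poor"
            shifts.append(z[tp1 & poor].mean() - z[tp1 & ~poor & tp1].mean())
        assert np.mean(shifts) == pytest.approx(effect, abs=0.75)

    def test_null_outcome_location_test(self):
        """With no planted effect, good and poor TP1 scores are exchangeable."""
        nonsig = 0
        for seed in range(20):
            cfg = GeneratorConfig(seed=seed, outcome_effect=0.0,
                                  n_patients_per_group=12, cells_per_sample=10,
                                  genes_per_cluster=5, n_cytokines=2,
                                  n_proteins=5, n_neutrophil_genes=5)
            _, truth = generate_cohort(cfg)
            meta = truth.meta.set_index("sample_id")
            z = truth.Z_true[cfg.outcome_factor_index]
            tp1 = meta["timepoint"] == "TP1"
            poor = meta["patient_id"].map(truth.outcome_labels) == "poor"
            p = stats.mannwhitneyu(z[tp1 & poor], z[tp1 & ~poor],
                                   alternative="two-sided").pvalue
            nonsig += p >= 0.01
        assert nonsig >= 18

    def test_missing_view_rate_zero_means_full_masks(self):
        cohort, truth = generate_cohort(GeneratorConfig(seed=0, **SMALL,
                                                        missing_view_rate=0.0))
        n = len(truth.meta)
        assert len(set(cohort.cells.cell_to_sample)) == n
        for v in cohort.views.values():
            assert len(v.values) == n

    def test_missing_view_rate_drops_samples_per_view(self):
        cohort, truth = generate_cohort(GeneratorConfig(seed=0, **SMALL,
                                                        missing_view_rate=0.25))
        n = len(truth.meta)
        expected = n - int(np.floor(0.25 * n))
        for v in cohort.views.values():
            assert len(v.values) == expected

    def test_oor_rate_approximate(self):
        cohort, _ = generate_cohort(GeneratorConfig(seed=0, oor_rate=0.1))
        rate = cohort.views["cytokines"].oor.to_numpy().mean()
        assert 0.05 < rate < 0.15

    def test_proteomics_missingness_is_left_censored(self):
        cohort, truth = generate_cohort(GeneratorConfig(seed=0,
                                                        protein_missing_rate=0.2))
        obs = cohort.views["proteomics"].values
        # reconstruct complete data to compare censored vs observed levels
        clean, _ = generate_cohort(GeneratorConfig(seed=0,
                                                   protein_missing_rate=0.0))
        full = clean.views["proteomics"].values.reindex(obs.index)
        zs = (full - full.mean()) / full.std()
        missing = obs.isna()
        rate = float(missing.to_numpy().mean())
        assert 0.15 < rate < 0.25
        # values behind missing entries sit below the observed ones
        assert zs.to_numpy()[missing.to_numpy()].mean() < -0.5


class TestSingleCell:
    def test_zero_scores_recover_baselines(self):
        cfg = GeneratorConfig(seed=0, n_patients_per_group=1,
                              cells_per_sample=4000, library_size_sd=0.0,
                              genes_per_cluster=30, n_cytokines=2,
                              n_proteins=5, n_neutrophil_genes=5)
        _, truth = generate_cohort(cfg)
        truth.Z_true.iloc[:, :] = 0.0
        cells = generate_single_cell_counts(cfg, truth,
                                            np.random.default_rng(5),
                                            samples=[truth.meta["sample_id"].iloc[0]])
        for c in range(cfg.n_clusters):
            sel = cells.cell_to_cluster == c
            genes = list(truth.W_true[f"cluster_{c}"].index)
            idx = [cells.genes.index(g) for g in genes]
            means = cells.dense()[sel][:, idx].mean(axis=0)
            expected = np.exp(truth.baselines[f"cluster_{c}"])
            rel_err = np.abs(means - expected) / expected
            assert np.quantile(rel_err, 0.9) < 0.05

    def test_library_factor_one_removes_depth_variation(self):
        cfg = GeneratorConfig(seed=1, library_size_sd=0.0, noise_free=True,
                              **SMALL)
        cohort, truth = generate_cohort(cfg)
        X = cohort.cells.dense()
        for c in range(cfg.n_clusters):
            for s in pd.unique(cohort.cells.cell_to_sample):
                sel = (cohort.cells.cell_to_cluster == c) & \
                      (cohort.cells.cell_to_sample == s)
                if sel.sum() >= 2:
                    assert np.ptp(X[sel].sum(axis=1)) < 1e-9

    def test_planted_abundance_shift_cluster0_declines(self):
        signs = 0
        for seed in range(10):
            cohort, truth = generate_cohort(GeneratorConfig(seed=seed, **SMALL))
            meta = cohort.meta.set_index("sample_id")
            frac = {}
            for s in pd.unique(cohort.cells.cell_to_sample):
                sel = cohort.cells.cell_to_sample == s
                frac[s] = (cohort.cells.cell_to_cluster[sel] == 0).mean()
            frac = pd.Series(frac)
            acs = meta.loc[frac.index]
            early = frac[(acs["timepoint"] == "TP1")].mean()
            late = frac[(acs["timepoint"] == "TP4")].mean()
            signs += early > late
        assert signs >= 9

    def test_noiseless_pseudobulk_reproduces_planted_structure(self):
        cfg = GeneratorConfig(seed=1, noise_free=True, library_size_sd=0.0,
                              missing_view_rate=0.0, oor_rate=0.0,
                              protein_missing_rate=0.0)
        cohort, truth = generate_cohort(cfg)
        views = pseudobulk(cohort.cells)
        for name, v in views.items():
            W = truth.W_true[name]
            Z = truth.Z_true.loc[v.values.index]
            pred = cfg.sc_effect_scale * (Z.to_numpy() @ W.to_numpy().T)
            obs = np.log(v.values[W.index].to_numpy())
            def dc(M):
                return M - M.mean(0) - M.mean(1, keepdims=True) + M.mean()
            r = np.corrcoef(dc(obs).ravel(), dc(pred).ravel())[0, 1]
            assert r > 0.99


class TestPriorNetwork:
    def test_planted_pairs_above_quantile(self):
        cohort, truth = generate_cohort(GeneratorConfig(seed=0, **SMALL))
        pot = cohort.network.potential
        threshold = np.quantile(pot.to_numpy().ravel(), 0.97)
        for ligand, target_feature in truth.planted_ligand_target_pairs:
            gene = target_feature.split("::")[1]
            assert pot.loc[ligand, gene] > threshold

    def test_planted_ligands_have_receptor_edges(self):
        cohort, truth = generate_cohort(GeneratorConfig(seed=0, **SMALL))
        for ligand, target_feature in truth.planted_ligand_target_pairs:
            receptors = cohort.network.receptors_of(ligand)
            assert truth.receptor_of_ligand[ligand] in receptors

    def test_decoy_only_network_retains_about_three_percent(self):
        cfg = GeneratorConfig(seed=0, n_planted_pairs=1, n_cytokines=100,
                              genes_per_cluster=50, n_patients_per_group=1,
                              cells_per_sample=10, n_proteins=5,
                              n_neutrophil_genes=5)
        _, truth = generate_cohort(cfg)
        truth.planted_ligand_target_pairs.clear()
        net = generate_prior_network(cfg, truth, np.random.default_rng(9))
        entries = net.potential.to_numpy().ravel()  # 100 x 100 = 10,000 iid
        threshold = np.quantile(entries, 0.97)
        frac = (entries >= threshold).mean()
        assert abs(frac - 0.03) < 0.01
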