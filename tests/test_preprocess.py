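"""Harmonization rules: pseudobulk, filters, normalizations, CLR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from immunofactor.io import ViewMatrix
from immunofactor.preprocess import (CellMatrix, FilterCriteria, MUNICH_GENE_FILTER,
                                     clr, clr_composition, compute_prevalence,
                                     equal_total_scaling, filter_genes,
                                     inverse_normal_transform_frame,
                                     normalize_pseudobulk, preprocess_clinical,
                                     preprocess_cytokines, preprocess_neutrophils,
                                     preprocess_proteomics, pseudobulk,
                                     quantile_normalize)


def view(df, name="v", oor=None):
    return ViewMatrix(name, df, oor=oor)


class TestPseudobulk:
    def test_mean_before_scaling(self):
        cells = CellMatrix(np.array([[2], [4]]), ["g"],
                           np.array(["s1", "s1"]), np.array([0, 0]))
        vb = pseudobulk(cells)["cluster_0"]
        # single sample: equal-total scaling is the identity
        assert vb.values.loc["s1", "g"] == 3.0

    def test_equal_total_scaling_targets_mean_of_totals(self):
        df = pd.DataFrame([[4.0, 6.0], [8.0, 12.0]], index=["s1", "s2"],
                          columns=["g1", "g2"])
        out = equal_total_scaling(df)
        # totals 10 and 20 -> common target 15: factors 1.5 and 0.75
        assert np.allclose(out.loc["s1"], [6.0, 9.0])
        assert np.allclose(out.loc["s2"], [6.0, 9.0])
        assert np.allclose(out.sum(axis=1), 15.0)

    def test_missing_sample_cluster_pair_is_absent_not_zero(self):
        cells = CellMatrix(np.array([[1], [2], [3]]), ["g"],
                           np.array(["s1", "s1", "s2"]), np.array([0, 0, 1]))
        views = pseudobulk(cells)
        assert "s2" not in views["cluster_0"].values.index
        assert "s1" not in views["cluster_1"].values.index


class TestPrevalenceAndFilter:
    def test_prevalence_examples(self):
        counts = np.array([[1, 0], [2, 0], [5, 0], [0, 0]])
        cells = CellMatrix(counts, ["g1", "g2"], np.array(["s"] * 4), np.zeros(4, int))
        prev = compute_prevalence(cells).set_index("gene")
        assert prev.loc["g1", "pct_cells_expressing"] == 75.0
        assert prev.loc["g1", "n_cells_expressing"] == 3
        assert prev.loc["g2", "pct_cells_expressing"] == 0.0

    def test_prevalence_matches_brute_force(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(0.8, size=(50, 6))
        clusters = rng.integers(0, 2, size=50)
        cells = CellMatrix(counts, [f"g{i}" for i in range(6)],
                           np.array([f"s{i % 3}" for i in range(50)]), clusters)
        prev = compute_prevalence(cells)
        for _, row in prev.iterrows():
            sel = clusters == row["cluster"]
            j = int(row["gene"][1:])
            n = int((counts[sel, j] > 0).sum())
            assert row["n_cells_expressing"] == n
            assert row["pct_cells_expressing"] == pytest.approx(100 * n / sel.sum())

    @pytest.mark.parametrize("pct,n,kept", [
        (60, 1500, True),   # first AND-pair
        (45, 2000, False),  # fails both pairs
        (41, 3100, True),   # second AND-pair
        (50, 2500, False),  # boundary: strict inequality on pct, n fails pair 2
        (60, 1200, False),  # boundary: strict inequality on n
    ])
    def test_gene_filter_forced_outcomes(self, pct, n, kept):
        prev = pd.DataFrame({"cluster": [0], "gene": ["g"],
                             "n_cells_expressing": [n], "pct_cells_expressing": [pct]})
        assert (filter_genes(prev, MUNICH_GENE_FILTER)[0] == ["g"]) is kept

    def test_filter_idempotent(self):
        rng = np.random.default_rng(0)
        prev = pd.DataFrame({
            "cluster": 0, "gene": [f"g{i}" for i in range(30)],
            "n_cells_expressing": rng.integers(0, 5000, 30),
            "pct_cells_expressing": rng.uniform(0, 100, 30),
        })
        once = filter_genes(prev, MUNICH_GENE_FILTER)[0]
        again = filter_genes(prev[prev["gene"].isin(once)], MUNICH_GENE_FILTER)
        assert again.get(0, []) == once


class TestQuantileNormalization:
    def test_identical_samples_unchanged(self):
        df = pd.DataFrame([[1.0, 5.0, 2.0]] * 2, index=["a", "b"])
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df, check_names=False)

    def test_rows_become_reference(self):
        df = np.log1p(pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
                                   index=["a", "b"]))
        out = quantile_normalize(df)
        ref = np.sort(df.to_numpy(), axis=1).mean(axis=0)
        assert np.allclose(np.sort(out.loc["a"]), ref)
        assert np.allclose(out.loc["a"], out.loc["b"])  # same ranks -> identical

    def test_monotone_order_preserved_and_sorted_rows_identical(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(5, 40)))
        out = quantile_normalize(df)
        for i in range(5):
            assert (np.argsort(out.iloc[i].to_numpy(), kind="stable")
                    == np.argsort(df.iloc[i].to_numpy(), kind="stable")).all()
        sorted_rows = np.sort(out.to_numpy(), axis=1)
        assert np.allclose(sorted_rows, sorted_rows[0])

    def test_ties_share_mean_of_spanned_reference(self):
        df = pd.DataFrame([[1.0, 1.0, 2.0], [10.0, 20.0, 30.0]])
        out = quantile_normalize(df)
        ref = np.sort(df.to_numpy(), axis=1).mean(axis=0)
        assert out.iloc[0, 0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out.iloc[0, 1] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out.iloc[0, 2] == pytest.approx(ref[2])


class TestCytokines:
    def test_log1p_of_zero_and_oor_to_zero(self):
        vals = pd.DataFrame({"c1": [0.0, np.e - 1], "c2": [np.nan, 1.0]},
                            index=["s1", "s2"])
        oor = pd.DataFrame({"c1": [False, False], "c2": [True, False]},
                           index=["s1", "s2"])
        out = preprocess_cytokines(view(vals, "cytokines", oor), 0.2)
        assert out.values.loc["s1", "c1"] == 0.0
        assert out.values.loc["s2", "c1"] == pytest.approx(1.0)
        assert out.values.loc["s1", "c2"] == 0.0  # OOR -> 0 -> log1p 0

    def test_low_validity_cytokine_removed_before_substitution(self):
        n = 20
        vals = pd.DataFrame({"lowc": [1.0] * 3 + [np.nan] * (n - 3),
                             "ok": np.ones(n)},
                            index=[f"s{i}" for i in range(n)])
        oor = pd.DataFrame(False, index=vals.index, columns=vals.columns)
        # 3/20 = 15% valid -> removed; OOR entries count as invalid
        oor.loc["s0", "lowc"] = True
        out = preprocess_cytokines(view(vals, "cytokines", oor), 0.2)
        assert list(out.values.columns) == ["ok"]

    def test_validity_boundary_is_strict_less_than(self):
        n = 10
        vals = pd.DataFrame({"c": [1.0] * 2 + [np.nan] * (n - 2)},
                            index=[f"s{i}" for i in range(n)])
        out = preprocess_cytokines(view(vals, "cytokines"), 0.2)
        assert list(out.values.columns) == ["c"]  # exactly 20% valid is kept


class TestNeutrophils:
    def test_gene_and_sample_rules_forced(self):
        rng = np.random.default_rng(0)
        n = 100
        df = pd.DataFrame(rng.poisson(30, size=(n, 10)) + 1.0,
                          index=[f"s{i}" for i in range(n)],
                          columns=[f"N{j}" for j in range(10)])
        df.loc[df.index[:21], "N0"] = 0.0  # expressed in 79% of samples -> dropped
        out = preprocess_neutrophils(view(df, "neutrophils"))
        assert "N0" not in out.values.columns

    def test_sample_coverage_rule(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.poisson(30, size=(20, 20)) + 1.0,
                          index=[f"s{i}" for i in range(20)],
                          columns=[f"N{j}" for j in range(20)])
        df.loc["s0", df.columns[:3]] = 0.0  # reads in 85% of genes -> dropped
        out = preprocess_neutrophils(view(df, "neutrophils"))
        assert out.values.loc["s0"].isna().all()

    def test_flagged_prefixes_dropped(self):
        df = pd.DataFrame(np.ones((4, 3)) + np.arange(4)[:, None],
                          columns=["MT-X", "RPL9", "N1"],
                          index=[f"s{i}" for i in range(4)])
        df["N2"] = [1.0, 2.0, 4.0, 8.0]
        out = preprocess_neutrophils(view(df, "neutrophils"))
        assert set(out.values.columns) <= {"N1", "N2"}

    def test_variance_quantile_drops_lowest_quarter(self):
        rng = np.random.default_rng(2)
        n = 40
        base = rng.poisson(20, size=(n, 8)).astype(float) + 1.0
        df = pd.DataFrame(base, index=[f"s{i}" for i in range(n)],
                          columns=[f"N{j}" for j in range(8)])
        # engineer a clean variance ordering post-log by scaling spreads
        med = df.median(axis=0)
        for j, col in enumerate(df.columns):
            df[col] = med[col] + (df[col] - med[col]) * (0.2 + 0.4 * j)
        df = df.clip(lower=0.5)
        out = preprocess_neutrophils(view(df, "neutrophils"))
        # 8 genes, 25% quantile: the two lowest-variance genes are dropped
        assert out.values.shape[1] == 6
        assert {"N0", "N1"}.isdisjoint(out.values.columns)

    def test_all_samples_removed_is_an_error(self):
        df = pd.DataFrame([[0.0, 30.0], [30.0, 0.0]], index=["s1", "s2"],
                          columns=["N1", "N2"])
        with pytest.raises(ValueError, match="every sample"):
            preprocess_neutrophils(view(df, "neutrophils"),
                                   min_gene_sample_fraction=0.0)


class TestProteomics:
    def test_low_validity_protein_removed(self):
        n = 10
        df = pd.DataFrame({"p_low": [1.0] * 7 + [np.nan] * 3,
                           "p_ok": np.arange(n, dtype=float)},
                          index=[f"s{i}" for i in range(n)])
        out = preprocess_proteomics(view(df, "proteomics"), seed=0)
        assert "p_low" not in out.values.columns  # 70% valid < 80%

    def test_no_missing_returns_median_centered_input(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(20, 1, size=(12, 4)),
                          index=[f"s{i}" for i in range(12)],
                          columns=[f"p{j}" for j in range(4)])
        out = preprocess_proteomics(view(df, "proteomics"), seed=0)
        expected = df - df.median(axis=0)
        assert np.allclose(out.values, expected)

    def test_downshift_imputation_distribution(self):
        # observed values with sample mean exactly 0 and SD (ddof=1) exactly 1
        n_obs, n_miss = 40_000, 10_000
        n = n_obs + n_miss
        q = stats.norm.ppf((np.arange(n_obs) + 0.5) / n_obs)
        q = (q - q.mean()) / q.std(ddof=1)
        col = np.concatenate([q, np.full(n_miss, np.nan)])
        # companion complete proteins keep incomplete samples above the
        # 80% sample-validity rule
        df = pd.DataFrame({"p": col, **{f"q{j}": np.zeros(n) for j in range(4)}},
                          index=[f"s{i}" for i in range(n)])
        out = preprocess_proteomics(view(df, "proteomics"), seed=7)
        imputed = out.values["p"].to_numpy()[n_obs:]
        assert abs(imputed.mean() + 1.8) < 0.02
        assert abs(imputed.std(ddof=1) - 0.3) < 0.02

    def test_constant_protein_imputes_constant(self):
        df = pd.DataFrame({"p": [5.0] * 9 + [np.nan],
                           **{f"q{j}": np.arange(10.0) for j in range(4)}},
                          index=[f"s{i}" for i in range(10)])
        out = preprocess_proteomics(view(df, "proteomics"), seed=0)
        assert np.allclose(out.values["p"], 0.0)  # median-centered constant

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(20, 3)),
                          index=[f"s{i}" for i in range(20)],
                          columns=list("abc"))
        df.iloc[::7, 1] = np.nan
        a = preprocess_proteomics(view(df.copy(), "proteomics"), seed=3)
        b = preprocess_proteomics(view(df.copy(), "proteomics"), seed=3)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestClinical:
    def test_log1p_values(self):
        df = pd.DataFrame({"CK": [0.0, np.e - 1]}, index=["s1", "s2"])
        out = preprocess_clinical(view(df, "clinical"))
        assert out.values["CK"].tolist() == pytest.approx([0.0, 1.0])

    def test_negative_is_an_error(self):
        df = pd.DataFrame({"CK": [-1.0]}, index=["s1"])
        with pytest.raises(ValueError, match="negative"):
            preprocess_clinical(view(df, "clinical"))


class TestInverseNormalTransform:
    def test_three_values_exact(self):
        df = pd.DataFrame({"f": [5.0, 2.0, 9.0]})
        out = inverse_normal_transform_frame(df)["f"].to_numpy()
        assert np.round(out, 4).tolist() == [0.0, -0.6745, 0.6745]

    def test_average_rank_ties(self):
        df = pd.DataFrame({"f": [1.0, 1.0, 2.0]})
        out = inverse_normal_transform_frame(df)["f"].to_numpy()
        tie = stats.norm.ppf(1.5 / 4)
        assert out[:2] == pytest.approx([tie, tie])
        assert out[2] == pytest.approx(stats.norm.ppf(3 / 4))

    @given(st.lists(st.floats(-1e3, 1e3).map(lambda v: round(v, 3)),
                    min_size=3, max_size=40, unique=True))
    def test_invariant_under_strictly_monotone_transform(self, values):
        df = pd.DataFrame({"f": values})
        direct = inverse_normal_transform_frame(df)
        # x + arctan(x): strictly increasing with derivative >= 1, so the
        # minimum spacing of the inputs is preserved and ranks are unchanged
        warped = inverse_normal_transform_frame(df + np.arctan(df))
        assert np.allclose(direct["f"], warped["f"])

    def test_mean_near_zero_odd_n_no_ties(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"f": rng.normal(size=41)})
        out = inverse_normal_transform_frame(df)
        assert abs(out["f"].mean()) < 1e-9

    def test_constant_feature_maps_to_zero_and_missing_untouched(self):
        df = pd.DataFrame({"f": [3.0, 3.0, np.nan, 3.0]})
        out = inverse_normal_transform_frame(df)
        assert out["f"].dropna().tolist() == [0.0, 0.0, 0.0]
        assert np.isnan(out["f"].iloc[2])


class TestCLR:
    def test_equal_proportions_map_to_zero(self):
        assert np.allclose(clr(np.full(4, 0.25)), 0.0)

    def test_worked_proportions(self):
        out = clr(np.array([0.5, 0.25, 0.25]))
        assert np.round(out, 4).tolist() == [0.4621, -0.231, -0.231]

    def test_rows_sum_to_zero_and_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(6, 5)).astype(float)
        cells_s, cells_c = [], []
        for i in range(6):
            for c in range(5):
                cells_s += [f"s{i}"] * int(counts[i, c])
                cells_c += [c] * int(counts[i, c])
        cm = CellMatrix(np.ones((len(cells_s), 1)), ["g"],
                        np.array(cells_s), np.array(cells_c))
        table = clr_composition(cm)
        assert np.abs(table.sum(axis=1)).max() < 1e-10
        perm = [3, 0, 4, 1, 2]
        cm2 = CellMatrix(np.ones((len(cells_s), 1)), ["g"], np.array(cells_s),
                         np.array([perm.index(c) for c in cells_c]))
        table2 = clr_composition(cm2)
        for new_c, old_c in enumerate(perm):
            assert np.allclose(table2[f"cluster_{perm.index(old_c)}"],
                               table[f"cluster_{old_c}"])


class TestNormalizePseudobulk:
    def test_masked_rows_stay_masked(self):
        ids = ["s1", "s2", "s3"]
        df = pd.DataFrame([[1.0, 2.0], [2.0, 4.0], [np.nan, np.nan]],
                          index=ids, columns=["g1", "g2"])
        out = normalize_pseudobulk(ViewMatrix("cluster_0", df))
        assert out.values.loc["s3"].isna().all()
        assert out.values.loc[["s1", "s2"]].notna().all().all()
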