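"""ANOVA, heritability, descriptives, correlations, PCA and clustering."""

import numpy as np
import pandas as pd
import pytest

from phenoscreen.screening_stats import (
    correlation_matrix,
    descriptive_stats,
    genotype_trait_means,
    heritability,
    pca,
    row_zscore,
    select_genotypes,
    two_way_anova,
    ward_cluster,
)
from phenoscreen.synthetic_data import SimModel, simulate_trait_table


class TestTwoWayAnova:
    def test_hand_computed_2x2x2_decomposition(self, small_table):
        """Explicit textbook sums of squares for the hand-set dataset.

        Grand mean 11; genotype means 9.5/12.5 -> SS_G = 18; treatment
        means 13/9 -> SS_C = 32; cell means 11, 8, 15, 10 -> cell SS 52,
        interaction 2; total SS 60, error 8.
        """
        res = two_way_anova(small_table, "y")
        t = res.table
        assert t.loc["genotype", "sum_sq"] == pytest.approx(18.0, abs=1e-10)
        assert t.loc["concentration", "sum_sq"] == pytest.approx(32.0, abs=1e-10)
        assert t.loc["genotype:concentration", "sum_sq"] == pytest.approx(2.0, abs=1e-10)
        assert t.loc["error", "sum_sq"] == pytest.approx(8.0, abs=1e-10)
        assert list(t["df"]) == [1, 1, 1, 4]
        assert t.loc["genotype", "F"] == pytest.approx(9.0)
        assert t.loc["concentration", "F"] == pytest.approx(16.0)
        assert t.loc["genotype:concentration", "F"] == pytest.approx(1.0)
        assert t.loc["concentration", "ss_pct"] == pytest.approx(100 * 32 / 60)

    def test_matches_statsmodels_on_random_data(self):
        statsmodels_formula = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        model = SimModel(n_genotypes=6, n_reps=3, sigma2_gc=0.5, seed=21)
        table, _ = simulate_trait_table(model, ["t"])
        ours = two_way_anova(table, "t").table
        fit = statsmodels_formula.ols(
            "t ~ C(genotype) * C(treatment)", data=table
        ).fit()
        ref = anova_lm(fit, typ=2)
        assert ours.loc["genotype", "sum_sq"] == pytest.approx(
            ref.loc["C(genotype)", "sum_sq"]
        )
        assert ours.loc["concentration", "sum_sq"] == pytest.approx(
            ref.loc["C(treatment)", "sum_sq"]
        )
        assert ours.loc["genotype:concentration", "sum_sq"] == pytest.approx(
            ref.loc["C(genotype):C(treatment)", "sum_sq"]
        )
        assert ours.loc["error", "sum_sq"] == pytest.approx(ref.loc["Residual", "sum_sq"])

    def test_ss_pct_partition_sums_to_100(self, rng):
        model = SimModel(n_genotypes=8, n_reps=3, sigma2_gc=1.0, seed=int(rng.integers(1e6)))
        table, _ = simulate_trait_table(model, ["t"])
        assert two_way_anova(table, "t").table["ss_pct"].sum() == pytest.approx(
            100.0, abs=1e-6
        )

    def test_concentration_only_limit(self):
        model = SimModel(
            n_genotypes=10, n_reps=3, sigma2_g=0.0, sigma2_gc=0.0,
            sigma2_e=1e-8, conc_effect=-5.0, seed=3,
        )
        table, _ = simulate_trait_table(model, ["t"])
        t = two_way_anova(table, "t").table
        assert t.loc["concentration", "ss_pct"] > 99.9
        assert t.loc["genotype", "ss_pct"] < 0.05

    def test_label_shuffle_within_treatment_keeps_concentration_ss(self, rng):
        model = SimModel(n_genotypes=6, n_reps=2, seed=8)
        table, _ = simulate_trait_table(model, ["t"])
        shuffled = table.copy()
        for treat in ("control", "deficient"):
            sel = shuffled["treatment"] == treat
            block = shuffled.loc[sel, "t"].to_numpy()
            shuffled.loc[sel, "t"] = rng.permutation(block)
        a = two_way_anova(table, "t").table.loc["concentration", "sum_sq"]
        b = two_way_anova(shuffled, "t").table.loc["concentration", "sum_sq"]
        assert a == pytest.approx(b)

    def test_unbalanced_design_rejected(self, small_table):
        with pytest.raises(ValueError, match="unbalanced"):
            two_way_anova(small_table.iloc[:-1], "y")


class TestHeritability:
    def test_zero_within_genotype_variance_gives_100(self):
        rows = [
            {"genotype": g, "treatment": "control", "rep": r, "t": v}
            for g, v in (("A", 5.0), ("B", 9.0), ("C", 7.0))
            for r in (1, 2, 3)
        ]
        vc = heritability(pd.DataFrame(rows), "t", "control")
        assert vc.H2_pct == pytest.approx(100.0)
        assert vc.sigma2_e == 0.0

    def test_no_genotype_signal_truncates_to_zero(self):
        # identical genotype means, all variance within replicates
        rows = [
            {"genotype": g, "treatment": "control", "rep": r, "t": v}
            for g in ("A", "B", "C")
            for r, v in ((1, 4.0), (2, 6.0))
        ]
        vc = heritability(pd.DataFrame(rows), "t", "control")
        assert vc.sigma2_g == 0.0
        assert vc.H2_pct == 0.0

    def test_recovery_near_plugin_truth(self):
        model = SimModel(
            n_genotypes=500, n_reps=5, sigma2_g=4.0, sigma2_gc=0.0,
            sigma2_e=1.0, seed=17,
        )
        table, _ = simulate_trait_table(model, ["t"])
        vc = heritability(table, "t", "control")
        assert vc.H2_pct == pytest.approx(100 * 4 / (4 + 1 / 5), abs=3.0)

    def test_sigma2_p_identity(self):
        model = SimModel(n_genotypes=10, n_reps=4, seed=2)
        table, _ = simulate_trait_table(model, ["t"])
        vc = heritability(table, "t", "deficient")
        assert vc.sigma2_p == pytest.approx(vc.sigma2_g + vc.sigma2_e / vc.r)
        assert 0.0 <= vc.H2_pct <= 100.0

    def test_single_replicate_rejected(self):
        rows = [
            {"genotype": g, "treatment": "control", "rep": 1, "t": 1.0}
            for g in ("A", "B")
        ]
        with pytest.raises(ValueError, match="2 replicates"):
            heritability(pd.DataFrame(rows), "t", "control")


class TestDescriptiveStats:
    def test_simple_numbers(self):
        rows = [
            {"genotype": g, "treatment": "control", "rep": 1, "t": v}
            for g, v in (("A", 1.0), ("B", 2.0), ("C", 3.0))
        ]
        rows += [dict(r, rep=2) for r in rows]
        out = descriptive_stats(pd.DataFrame(rows), "t", "control")
        assert out["mean"] == pytest.approx(2.0)
        assert out["CV_pct"] == pytest.approx(100 * out["sd"] / 2.0)

    def test_constant_data(self):
        rows = [
            {"genotype": g, "treatment": "control", "rep": r, "t": 5.0}
            for g in ("A", "B") for r in (1, 2)
        ]
        out = descriptive_stats(pd.DataFrame(rows), "t", "control")
        assert out["sd"] == 0.0
        assert out["CV_pct"] == 0.0
        assert np.isnan(out["skewness"])

    def test_gcv_recovers_truth(self):
        model = SimModel(
            n_genotypes=400, n_reps=4, mu=50.0, sigma2_g=9.0, sigma2_gc=0.0,
            sigma2_e=1.0, seed=23,
        )
        table, _ = simulate_trait_table(model, ["t"])
        out = descriptive_stats(table, "t", "control")
        assert out["GCV_pct"] == pytest.approx(100 * 3.0 / 50.0, rel=0.10)


class TestCorrelationMatrix:
    def make_means(self, rng, n=12):
        return pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.normal(size=n)},
            index=[f"G{i}" for i in range(n)],
        )

    def test_duplicated_and_negated_columns(self, rng):
        means = self.make_means(rng)
        means["a2"] = means["a"]
        means["neg"] = -means["a"]
        r, p = correlation_matrix(means)
        assert r.loc["a", "a2"] == pytest.approx(1.0)
        assert r.loc["a", "neg"] == pytest.approx(-1.0)
        assert np.allclose(r.to_numpy(), r.to_numpy().T)
        assert (np.diag(r) == 1.0).all()

    def test_independent_traits_weakly_correlated(self):
        rng = np.random.default_rng(6)
        means = pd.DataFrame(
            {"x": rng.normal(size=1000), "y": rng.normal(size=1000)}
        )
        r, _ = correlation_matrix(means)
        assert abs(r.loc["x", "y"]) < 0.1

    def test_constant_trait_marked_missing(self, rng):
        means = self.make_means(rng)
        means["const"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            r, p = correlation_matrix(means)
        assert r.loc["const"].isna().all()

    def test_bonferroni_inflates_p(self, rng):
        means = self.make_means(rng, n=10)
        means["c"] = rng.normal(size=10)
        _, p_raw = correlation_matrix(means)
        _, p_adj = correlation_matrix(means, bonferroni=True)
        off = ~np.eye(len(p_raw), dtype=bool)
        assert (p_adj.to_numpy()[off] >= p_raw.to_numpy()[off] - 1e-15).all()


class TestPca:
    def test_rank_one_data_loads_on_single_component(self):
        t = np.arange(8, dtype=float)
        matrix = pd.DataFrame({"a": t, "b": 2 * t, "c": -t})
        res = pca(matrix, standardize=False)
        assert res.explained_pct.iloc[0] == pytest.approx(100.0)

    def test_explained_sums_to_100_and_non_increasing(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(10, 5)))
        res = pca(matrix)
        assert res.explained_pct.sum() == pytest.approx(100.0)
        assert (np.diff(res.explained_pct.to_numpy()) <= 1e-12).all()

    def test_full_rank_reconstruction(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(6, 4)))
        res = pca(matrix, standardize=False)
        centered = matrix - matrix.mean()
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, centered.to_numpy(), atol=1e-8)

    def test_loadings_orthonormal_and_score_cov_diagonal(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(12, 4)))
        res = pca(matrix)
        l = res.loadings.to_numpy()
        assert np.allclose(l.T @ l, np.eye(l.shape[1]), atol=1e-8)
        cov = np.cov(res.scores.to_numpy(), rowvar=False)
        assert np.allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(9, 3)))
        res = pca(matrix)
        for comp in res.loadings.columns:
            v = res.loadings[comp].to_numpy()
            assert v[np.abs(v).argmax()] > 0

    def test_missing_values_rejected(self):
        matrix = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            pca(matrix)

    def test_constant_column_with_standardize_rejected(self):
        matrix = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            pca(matrix, standardize=True)


class TestSelectGenotypes:
    def planted_panel(self, rng):
        # four groups planted in the corners of trait space; unequal spreads
        # keep the principal axes aligned with the planted directions
        centers = [(4, 2), (-4, 2), (-4, -2), (4, -2)]
        rows, names = [], []
        for gi, (cx, cy) in enumerate(centers):
            for j in range(4):
                names.append(f"G{gi}{j}")
                rows.append(
                    [cx + rng.normal(0, 0.2), cy + rng.normal(0, 0.2),
                     rng.normal(0, 0.2)]
                )
        return pd.DataFrame(rows, columns=["t1", "t2", "t3"], index=names)

    def test_identical_genotypes_no_contrast(self):
        matrix = pd.DataFrame(
            {"t1": [5.0] * 4, "t2": [2.0] * 4}, index=list("ABCD")
        )
        res = pca(matrix, standardize=False)
        with pytest.raises(ValueError, match="no contrast"):
            select_genotypes(res, matrix, ["t1"])

    def test_dominant_genotype_flagged_superior_everywhere(self, rng):
        matrix = pd.DataFrame(
            rng.normal(size=(6, 3)), columns=["t1", "t2", "t3"],
            index=[f"G{i}" for i in range(6)],
        )
        matrix.loc["G0"] = matrix.max().to_numpy() + 1.0
        res = pca(matrix, standardize=False)
        labels, _ = select_genotypes(res, matrix, ["t1", "t2", "t3"])
        assert (labels.loc["G0", [f"superior_{t}" for t in ["t1", "t2", "t3"]]]
                == "superior").all()

    def test_planted_groups_cover_all_quadrants(self, rng):
        matrix = self.planted_panel(rng)
        res = pca(matrix, standardize=False)
        labels, selected = select_genotypes(res, matrix, ["t1", "t2"])
        occupied = set(labels["quadrant"])
        assert occupied == {"Q1", "Q2", "Q3", "Q4"}
        assert {labels.loc[g, "quadrant"] for g in selected} == occupied


class TestWardCluster:
    def test_row_zscore_definition(self, rng):
        matrix = pd.DataFrame(rng.normal(5, 2, size=(6, 8)))
        scaled = row_zscore(matrix)
        assert np.allclose(scaled.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(scaled.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_constant_row_named_in_error(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(3, 5)), index=["a", "flat", "c"])
        matrix.loc["flat"] = 7.0
        with pytest.raises(ValueError, match="flat"):
            row_zscore(matrix)

    def test_separated_clouds_recovered_perfectly(self, rng):
        a = rng.normal(0, 1, size=(10, 4))
        b = rng.normal(100, 1, size=(10, 4))  # 100 sd apart
        matrix = pd.DataFrame(
            np.vstack([a, b]), index=[f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        )
        res = ward_cluster(matrix, scale_rows=False, k=2)
        la = set(res.labels.iloc[:10])
        lb = set(res.labels.iloc[10:])
        assert len(la) == 1 and len(lb) == 1 and la != lb

    def test_merge_heights_non_decreasing(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(15, 4)))
        res = ward_cluster(matrix, scale_rows=False, k=3)
        heights = res.item_linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_item_order_invariance(self, rng):
        matrix = pd.DataFrame(
            rng.normal(size=(12, 5)), index=[f"G{i}" for i in range(12)]
        )
        res1 = ward_cluster(matrix, scale_rows=False, k=3)
        perm = rng.permutation(12)
        res2 = ward_cluster(matrix.iloc[perm], scale_rows=False, k=3)
        labels1 = res1.labels
        labels2 = res2.labels.reindex(labels1.index)
        # same partition up to label renaming
        mapping = {}
        for g in labels1.index:
            mapping.setdefault(labels2[g], set()).add(labels1[g])
        assert all(len(v) == 1 for v in mapping.values())
        assert len(mapping) == 3


def test_genotype_trait_means_shape():
    model = SimModel(n_genotypes=5, n_reps=2, seed=1)
    table, _ = simulate_trait_table(model, ["x", "y"])
    means = genotype_trait_means(table, "deficient")
    assert means.shape == (5, 2)
    sub = table[table.treatment == "deficient"]
    assert means.loc["G001", "x"] == pytest.approx(
        sub[sub.genotype == "G001"]["x"].mean()
    )
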