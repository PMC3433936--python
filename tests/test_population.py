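"""Group summaries, CpG correlation structure and PCA/ANOVA stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinmeth import SimConfig, anova_pc1, cpg_correlation_matrix, group_summary, pca_pc1
from twinmeth.simulate import simulate_population_cohort

from conftest import flat_spec, make_matrix


def _groups(matrix, labels):
    return pd.Series(labels, index=matrix.sample_ids)


class TestGroupSummary:
    def test_hand_arithmetic(self):
        m = make_matrix([[0.4], [0.6]])
        out = group_summary(m, _groups(m, ["g", "g"]))
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(0.5)
        assert row["sd"] == pytest.approx(0.1414, abs=1e-4)  # n-1 denominator
        assert row["n"] == 2

    def test_identical_groups_identical_rows(self):
        m = make_matrix([[0.2, 0.4], [0.6, 0.8], [0.2, 0.4], [0.6, 0.8]])
        out = group_summary(m, _groups(m, ["a", "a", "b", "b"]))
        a = out[out["group"] == "a"].drop(columns="group").reset_index(drop=True)
        b = out[out["group"] == "b"].drop(columns="group").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cell_marked_missing(self):
        m = make_matrix([[0.4], [np.nan]])
        out = group_summary(m, _groups(m, ["a", "b"]))
        assert np.isnan(out[out["group"] == "b"]["mean"].iloc[0])

    def test_unlabelled_sample_rejected(self):
        m = make_matrix([[0.4], [0.5]])
        with pytest.raises(ValueError, match="without a group"):
            group_summary(m, pd.Series({"s0": "a"}))

    def test_between_group_gap_shrinks_with_sample_size(self):
        def max_gap(n):
            cfg = SimConfig(seed=123, amplicons=(flat_spec(),),
                            n_pop_samples_per_group=n)
            m, meta = simulate_population_cohort(cfg)
            out = group_summary(m, meta.set_index("sample_id")["group"])
            return out.groupby("unit")["mean"].agg(np.ptp).max()
        assert max_gap(500) < max_gap(50)


class TestCorrelationMatrix:
    def test_diagonal_symmetry_and_latent_pair(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(0.5, 0.1, 200)
        vals = np.clip(np.column_stack([
            latent + rng.normal(0, 0.01, 200),
            latent + rng.normal(0, 0.01, 200),
            rng.normal(0.5, 0.1, 200),
        ]), 0, 1)
        m = make_matrix(vals, unit_ids=["A.u1", "A.u2", "B.u1"])
        corr = cpg_correlation_matrix(m)
        assert corr.loc["A.u1", "A.u1"] == 1.0
        assert corr.loc["A.u1", "A.u2"] == corr.loc["A.u2", "A.u1"]
        assert corr.loc["A.u1", "A.u2"] > 0.9  # shared latent, tiny noise

    def test_independent_units_weakly_correlated(self):
        """|r| between independent units at n=400 stays under 0.15 in at
        least 95% of Monte-Carlo replicates (null SE ~ 1/sqrt(399) ~ 0.05)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = make_matrix(np.clip(rng.normal(0.5, 0.08, (400, 2)), 0, 1),
                            unit_ids=["A.u1", "A.u2"])
            corr = cpg_correlation_matrix(m)
            hits += abs(corr.loc["A.u1", "A.u2"]) < 0.15
        assert hits >= 95

    def test_zero_variance_unit_marked_missing_with_warning(self, caplog):
        vals = np.column_stack([np.full(10, 0.5), np.linspace(0.3, 0.7, 10)])
        m = make_matrix(vals, unit_ids=["A.const", "A.ok"])
        with caplog.at_level("WARNING"):
            corr = cpg_correlation_matrix(m)
        assert np.isnan(corr.loc["A.const", "A.ok"])
        assert np.isnan(corr.loc["A.const", "A.const"])
        assert corr.loc["A.ok", "A.ok"] == 1.0
        assert "zero variance" in caplog.text

    def test_sparse_pairs_marked_missing(self):
        vals = np.full((4, 2), np.nan)
        vals[:, 0] = [0.1, 0.2, 0.3, 0.4]
        vals[:2, 1] = [0.3, 0.4]  # only 2 complete pairs < min_periods
        m = make_matrix(vals)
        corr = cpg_correlation_matrix(m, min_periods=3)
        assert np.isnan(corr.iloc[0, 1])


class TestPCA:
    def test_rank_one_data_explains_everything(self):
        base = np.linspace(0.2, 0.8, 5)
        m = make_matrix(np.column_stack([base, base, base]))
        res = pca_pc1(m, "A")
        assert res.variance_explained_pc1 == pytest.approx(1.0)

    def test_two_unit_toy_closed_form(self):
        # points (0,0), (.5,.5), (1,1): PC1 direction (1,1)/sqrt2,
        # centred scores proportional to (-1, 0, 1) * sqrt(2)/2
        m = make_matrix([[0, 0], [0.5, 0.5], [1.0, 1.0]])
        res = pca_pc1(m, "A")
        np.testing.assert_allclose(res.scores.to_numpy(),
                                   np.array([-1, 0, 1]) * np.sqrt(2) / 2,
                                   atol=1e-12)
        np.testing.assert_allclose(res.loadings.to_numpy(),
                                   [np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        m = make_matrix(np.clip(rng.normal(0.5, 0.1, (20, 6)), 0, 1))
        res = pca_pc1(m, "A")
        assert res.variance_explained.sum() == pytest.approx(1.0)
        assert res.scores.mean() == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(2)
        m = make_matrix(np.clip(rng.normal(0.5, 0.1, (30, 4)), 0, 1))
        res = pca_pc1(m, "A")
        lead = res.loadings.to_numpy()
        assert lead[np.argmax(np.abs(lead))] > 0

    def test_mean_imputation_preserves_sample_count(self):
        rng = np.random.default_rng(3)
        vals = np.clip(rng.normal(0.5, 0.1, (30, 4)), 0, 1)
        vals[0, 0] = np.nan
        m = make_matrix(vals)
        res = pca_pc1(m, "A", missing="impute")
        assert len(res.scores) == 30 and res.n_imputed_cells == 1
        res_cc = pca_pc1(m, "A", missing="complete")
        assert len(res_cc.scores) == 29

    def test_degenerate_covariance_rejected(self):
        m = make_matrix([[0.5, 0.6]] * 4)
        with pytest.raises(ValueError, match="degenerate covariance"):
            pca_pc1(m, "A")


class TestAnova:
    def test_identical_groups_no_effect(self):
        scores = pd.Series([1.0, 2, 3, 1, 2, 3], index=list("abcdef"))
        groups = pd.Series(list("111222"), index=list("abcdef"))
        res = anova_pc1(scores, groups)
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_rejects(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(np.r_[rng.normal(0, 1e-3, 10), 1 + rng.normal(0, 1e-3, 10)])
        groups = pd.Series(["a"] * 10 + ["b"] * 10)
        assert anova_pc1(scores, groups).p_value < 1e-10

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=40))
        groups = pd.Series(np.repeat(list("abcd"), 10))
        base = anova_pc1(scores, groups)
        rescaled = anova_pc1(3.5 * scores - 2.0, groups)
        assert rescaled.f_statistic == pytest.approx(base.f_statistic)
        assert rescaled.p_value == pytest.approx(base.p_value)

    def test_small_group_rejected(self):
        scores = pd.Series([1.0, 2, 3])
        groups = pd.Series(["a", "a", "b"])
        with pytest.raises(ValueError, match="2 samples per group"):
            anova_pc1(scores, groups)

    def test_welch_variant_close_under_equal_variances(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.normal(size=80))
        groups = pd.Series(np.repeat(list("abcd"), 20))
        classic = anova_pc1(scores, groups)
        welch = anova_pc1(scores, groups, welch=True)
        assert welch.p_value == pytest.approx(classic.p_value, abs=0.1)

    def test_null_district_pattern_non_significant(self):
        """Under a null 4-group population, every amplicon's PC1 ANOVA should
        be non-significant — the expected no-stratification outcome."""
        cfg = SimConfig(seed=2024, n_pop_samples_per_group=94)
        m, meta = simulate_population_cohort(cfg)
        groups = meta.set_index("sample_id")["group"]
        ps = [anova_pc1(pca_pc1(m, amp).scores, groups).p_value for amp in m.amplicons]
        assert min(ps) > 0.01


def test_pc1_matches_full_eigendecomposition_oracle():
    """PC1 scores agree (up to the fixed sign) with sklearn's PCA."""
    from sklearn.decomposition import PCA

    rng = np.random.default_rng(4)
    vals = np.clip(rng.normal(0.5, 0.1, (5, 5)), 0, 1)
    m = make_matrix(vals)
    res = pca_pc1(m, "A")
    oracle = PCA(n_components=5).fit(vals)
    s = np.sign(np.dot(oracle.components_[0], res.loadings.to_numpy()))
    np.testing.assert_allclose(res.scores.to_numpy(),
                               s * oracle.transform(vals)[:, 0], atol=1e-10)
    np.testing.assert_allclose(res.variance_explained_pc1,
                               oracle.explained_variance_ratio_[0], atol=1e-12)
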