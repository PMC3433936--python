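"""Within-pair discordance statistics, age trends and threshold tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from twinmeth import SimConfig, simulate_twin_cohort
from twinmeth.twins import (
    age_class_summary,
    age_trend,
    compute_pair_statistics,
    pair_correlation,
    pair_euclidean,
    threshold_test,
)

from conftest import flat_spec, make_matrix


def _two_member_matrix(x, y):
    return make_matrix(np.vstack([x, y]), sample_ids=["t1", "t2"],
                       unit_ids=[f"A.u{i}" for i in range(len(x))])


def _hand_pearson(x, y):
    x, y = np.asarray(x), np.asarray(y)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestPairCorrelation:
    def test_identical_vectors(self):
        m = _two_member_matrix([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        r, n, reason = pair_correlation(m, "t1", "t2", "A")
        assert r == pytest.approx(1.0) and n == 3 and reason is None

    def test_perfect_anti_order(self):
        m = _two_member_matrix([0.1, 0.2, 0.3], [0.3, 0.2, 0.1])
        r, _, _ = pair_correlation(m, "t1", "t2", "A")
        assert r == pytest.approx(-1.0)

    def test_matches_hand_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.random(5), rng.random(5)
            m = _two_member_matrix(x, y)
            r, _, _ = pair_correlation(m, "t1", "t2", "A")
            assert r == pytest.approx(_hand_pearson(x, y), abs=1e-12)

    def test_symmetric_in_member_order(self):
        rng = np.random.default_rng(1)
        m = _two_member_matrix(rng.random(6), rng.random(6))
        assert (pair_correlation(m, "t1", "t2", "A")
                == pair_correlation(m, "t2", "t1", "A"))

    def test_constant_vector_undefined(self):
        m = _two_member_matrix([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        r, _, reason = pair_correlation(m, "t1", "t2", "A")
        assert np.isnan(r) and reason == "constant member vector"

    def test_too_few_shared_units_undefined(self):
        m = _two_member_matrix([0.1, 0.2, np.nan], [0.3, np.nan, 0.1])
        r, n, reason = pair_correlation(m, "t1", "t2", "A")
        assert np.isnan(r) and n == 1 and "< 3" in reason


class TestPairEuclidean:
    def test_identical_vectors_zero(self):
        m = _two_member_matrix([0.1, 0.2], [0.1, 0.2])
        d, _, _ = pair_euclidean(m, "t1", "t2", "A")
        assert d == 0.0

    def test_hand_arithmetic(self):
        m = _two_member_matrix([0.4, 0.5], [0.7, 0.9])
        d, n, _ = pair_euclidean(m, "t1", "t2", "A")
        assert d == pytest.approx(0.5)  # sqrt(0.09 + 0.16)
        assert n == 2

    def test_no_shared_units_undefined(self):
        m = _two_member_matrix([np.nan, 0.2], [0.3, np.nan])
        d, n, reason = pair_euclidean(m, "t1", "t2", "A")
        assert np.isnan(d) and n == 0 and reason == "no shared units"

    @given(st.lists(st.tuples(*[st.floats(0, 1) for _ in range(3)]),
                    min_size=3, max_size=3))
    def test_triangle_inequality(self, rows):
        m = make_matrix(np.array(rows), sample_ids=["a", "b", "c"],
                        unit_ids=["A.u0", "A.u1", "A.u2"])
        dab, _, _ = pair_euclidean(m, "a", "b", "A")
        dbc, _, _ = pair_euclidean(m, "b", "c", "A")
        dac, _, _ = pair_euclidean(m, "a", "c", "A")
        assert dac <= dab + dbc + 1e-12

    def test_monotone_in_included_units(self):
        x, y = [0.1, 0.3, 0.5, 0.9], [0.2, 0.5, 0.4, 0.1]
        dists = []
        for k in range(1, 5):
            m = _two_member_matrix(x[:k], y[:k])
            d, _, _ = pair_euclidean(m, "t1", "t2", "A")
            dists.append(d)
        assert all(b >= a for a, b in zip(dists, dists[1:]))


def test_batch_statistics_agree_with_per_pair_operations():
    cfg = SimConfig(seed=21, n_mz_pairs=15, n_dz_pairs=10, missing_rate=0.1)
    m, _, pairs = simulate_twin_cohort(cfg)
    table = compute_pair_statistics(m, pairs)
    for _, row in table.iterrows():
        p = pairs[pairs["pair_id"] == row["pair_id"]].iloc[0]
        r, nr, _ = pair_correlation(m, p.member_1, p.member_2, row["amplicon"])
        d, nd, _ = pair_euclidean(m, p.member_1, p.member_2, row["amplicon"])
        assert (np.isnan(r) and np.isnan(row["pearson_r"])) or \
            row["pearson_r"] == pytest.approx(r, abs=1e-12)
        assert (np.isnan(d) and np.isnan(row["euclidean_d"])) or \
            row["euclidean_d"] == pytest.approx(d, abs=1e-12)
        assert row["n_shared_units"] == nd


def _stats_frame(values, ages, amplicon="A"):
    return pd.DataFrame({
        "pair_id": [f"p{i}" for i in range(len(values))],
        "amplicon": amplicon,
        "zygosity": "MZ",
        "age": ages,
        "years_apart": 0.0,
        "pearson_r": values,
        "euclidean_d": values,
        "n_shared_units": 5,
        "reason": None,
    })


class TestAgeTrend:
    def test_perfect_monotone_decrease(self):
        tr = age_trend(_stats_frame([0.9, 0.8, 0.7, 0.6], [30, 40, 50, 60]), "A")
        assert tr.spearman_rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(2)
        vals, ages = rng.random(10), rng.uniform(20, 90, 10)
        tr = age_trend(_stats_frame(vals, ages), "A")
        ranks_v = stats.rankdata(vals)
        ranks_a = stats.rankdata(ages)
        oracle = np.corrcoef(ranks_v, ranks_a)[0, 1]
        assert tr.spearman_rho == pytest.approx(oracle, abs=1e-12)

    def test_null_quantile_at_n30(self):
        """With no true age dependence, |rho| at n=30 stays below 0.36 in
        ~95% of replicates (0.36 ~ the two-sided 5% point of the null)."""
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            tr = age_trend(_stats_frame(rng.random(30), rng.uniform(20, 97, 30)), "A")
            hits += abs(tr.spearman_rho) < 0.36
        assert 0.92 <= hits / n_rep <= 0.98

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            age_trend(_stats_frame([0.1, 0.2, 0.3], [30, 40, 50]), "A")

    def test_all_tied_statistic_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            age_trend(_stats_frame([0.5] * 6, [30, 40, 50, 60, 70, 80]), "A")


class TestThresholdTest:
    def test_identical_groups_no_effect(self):
        frame = _stats_frame([0.1, 0.2, 0.3, 0.1, 0.2, 0.3],
                             [30, 40, 50, 65, 70, 80])
        res = threshold_test(frame, "A")
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert (res.n_young, res.n_old) == (3, 3)

    def test_undersized_group_named(self):
        frame = _stats_frame([0.1, 0.2, 0.3, 0.4], [30, 40, 50, 65])
        with pytest.raises(ValueError, match="age > threshold"):
            threshold_test(frame, "A")

    def test_welch_flag_runs(self):
        rng = np.random.default_rng(4)
        frame = _stats_frame(rng.random(20), np.r_[np.full(10, 40), np.full(10, 70)])
        classic = threshold_test(frame, "A", equal_var=True)
        welch = threshold_test(frame, "A", equal_var=False)
        assert welch.p_value == pytest.approx(classic.p_value, abs=0.05)


class TestAgeClassSummary:
    def test_boundary_assignment(self):
        m = make_matrix([[0.4, 0.5], [0.6, 0.7]], sample_ids=["x", "y"])
        ages = pd.Series({"x": 45, "y": 46})
        out = age_class_summary(m, ages)
        n = out.set_index("age_class")["n_samples"]
        assert n["20-45"] == 1 and n["46-60"] == 1

    def test_single_class_reduces_to_plain_summary(self):
        rng = np.random.default_rng(5)
        vals = np.clip(rng.normal(0.5, 0.05, (8, 3)), 0, 1)
        m = make_matrix(vals)
        ages = pd.Series(30.0, index=m.sample_ids)
        out = age_class_summary(m, ages, classes=[(20, 45)])
        assert out["n_samples"].iloc[0] == 8
        assert out["mean_methylation"].iloc[0] == pytest.approx(vals.mean())
        assert out["mean_unit_sd"].iloc[0] == pytest.approx(
            np.std(vals, axis=0, ddof=1).mean())

    def test_empty_class_reported_with_nan(self):
        m = make_matrix([[0.5]], sample_ids=["x"])
        out = age_class_summary(m, pd.Series({"x": 30}))
        empty = out[out["age_class"] == "76-97"]
        assert empty["n_samples"].iloc[0] == 0
        assert np.isnan(empty["mean_methylation"].iloc[0])

    def test_drift_amplicon_dispersion_grows_with_age(self):
        """The generator's variance arithmetic: with a x3 drift multiplier,
        per-unit SD in the oldest class exceeds the youngest class."""
        cfg = SimConfig(seed=6, n_mz_pairs=200, n_dz_pairs=0,
                        amplicons=(flat_spec("drift", drift_multiplier=3.0),
                                   flat_spec("calm")))
        m, meta, _ = simulate_twin_cohort(cfg)
        ages = meta.set_index("sample_id")["age"]
        out = age_class_summary(m, ages).set_index(["amplicon", "age_class"])
        assert (out.loc[("drift", "76-97"), "mean_unit_sd"]
                > out.loc[("drift", "20-45"), "mean_unit_sd"])


def test_sex_stratified_subset_matches_full_run():
    """Computing statistics on a sex subset equals subsetting the full table."""
    cfg = SimConfig(seed=7)
    m, _, pairs = simulate_twin_cohort(cfg)
    full = compute_pair_statistics(m, pairs)
    males = pairs[(pairs["sex_1"] == "M") & (pairs["sex_2"] == "M")]
    sub = compute_pair_statistics(m, males)
    merged = full[full["pair_id"].isin(males["pair_id"])].reset_index(drop=True)
    pd.testing.assert_frame_equal(
        sub.sort_values(["pair_id", "amplicon"]).reset_index(drop=True),
        merged.sort_values(["pair_id", "amplicon"]).reset_index(drop=True),
    )
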