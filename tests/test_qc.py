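"""Cleaning rules: sample coverage, unit missingness, bimodality detection."""

import numpy as np
import pandas as pd
import pytest

from twinmeth import QCConfig, run_qc
from twinmeth.qc import detect_bimodal_units, filter_samples, filter_units

from conftest import make_matrix


def _complete_matrix(n=60, k=50, seed=0):
    rng = np.random.default_rng(seed)
    vals = np.clip(0.5 + 0.05 * rng.standard_normal((n, k)), 0, 1)
    return make_matrix(vals)


class TestFilterSamples:
    def test_below_threshold_removed_boundary_kept(self):
        m = _complete_matrix(3, 50)
        vals = m.data.to_numpy()
        vals[0, :30] = np.nan   # 20/50 measured = 40% -> removed
        vals[1, :20] = np.nan   # 30/50 measured = 60% -> kept (strict <)
        m = make_matrix(vals)
        out, removed = filter_samples(m, 0.60)
        assert [s for s, _ in removed] == ["s0"]
        assert removed[0][1] == pytest.approx(0.40)
        assert out.sample_ids == ["s1", "s2"]

    def test_fully_observed_identity(self):
        m = _complete_matrix()
        out, removed = filter_samples(m)
        assert removed == []
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_samples(make_matrix(np.empty((0, 0))))


class TestFilterUnits:
    def test_above_threshold_removed_boundary_kept(self):
        m = _complete_matrix(100, 3)
        vals = m.data.to_numpy()
        vals[:31, 0] = np.nan  # 31% missing -> removed (strict >)
        vals[:30, 1] = np.nan  # 30% missing -> kept
        m = make_matrix(vals)
        out, removed = filter_units(m, 0.30)
        assert [u for u, _ in removed] == ["A.u0"]
        assert removed[0][1] == pytest.approx(0.31)
        assert out.unit_ids == ["A.u1", "A.u2"]

    def test_complete_matrix_identity(self):
        m = _complete_matrix()
        out, removed = filter_units(m)
        assert removed == []
        assert out.unit_ids == m.unit_ids


class TestBimodalDetector:
    def test_unimodal_rarely_flagged_bimodal_reliably_flagged(self):
        """Monte-Carlo over 100 seeds: a N(0.5, 0.05) unit passes, an
        equal-weight two-mode unit at 0.2/0.8 is caught."""
        false_pos = true_pos = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            uni = np.clip(rng.normal(0.5, 0.05, 200), 0, 1)
            comp = rng.integers(0, 2, 200)
            bim = np.clip(rng.normal(np.where(comp, 0.8, 0.2), 0.05), 0, 1)
            m = make_matrix(np.column_stack([uni, bim]), unit_ids=["A.uni", "A.bim"])
            flagged, _ = detect_bimodal_units(m)
            names = {f.unit for f in flagged}
            false_pos += "A.uni" in names
            true_pos += "A.bim" in names
        assert true_pos >= 0.95 * n_seeds
        assert false_pos <= 0.05 * n_seeds

    def test_constant_unit_skipped_as_degenerate(self):
        m = make_matrix(np.column_stack([
            np.full(30, 0.5), np.linspace(0.3, 0.7, 30)
        ]), unit_ids=["A.const", "A.ok"])
        flagged, skipped = detect_bimodal_units(m)
        assert flagged == []
        assert ("A.const", "zero variance (degenerate)") in skipped

    def test_sparse_unit_skipped_with_count(self):
        vals = np.column_stack([np.linspace(0.2, 0.8, 30)])
        vals[10:, 0] = np.nan
        m = make_matrix(vals, unit_ids=["A.sparse"])
        flagged, skipped = detect_bimodal_units(m, min_n=20)
        assert flagged == []
        assert skipped[0][0] == "A.sparse" and "10" in skipped[0][1]


def engineered_fixture():
    """60 samples x 50 units with exactly three QC defects:

    * sample s0 at 40% coverage (30 missing units, none of them B.u5),
    * unit B.u5 missing in 19 of the 59 surviving samples (32.2% > 30%),
    * unit C.u3 bimodal (modes 0.25 / 0.75).
    """
    rng = np.random.default_rng(42)
    units = ([f"A.u{j}" for j in range(8)] + [f"B.u{j}" for j in range(16)]
             + [f"C.u{j}" for j in range(8)] + [f"D.u{j}" for j in range(18)])
    vals = np.clip(0.5 + 0.05 * rng.standard_normal((60, 50)), 0, 1)
    cols = {u: i for i, u in enumerate(units)}
    sparse_sample_units = [i for u, i in cols.items() if u != "B.u5"][:30]
    vals[0, sparse_sample_units] = np.nan
    vals[1:20, cols["B.u5"]] = np.nan
    comp = rng.integers(0, 2, 60)
    vals[:, cols["C.u3"]] = np.clip(
        rng.normal(np.where(comp, 0.75, 0.25), 0.04), 0, 1)
    return make_matrix(vals, unit_ids=units)


class TestRunQC:
    def test_clean_fixture_untouched(self):
        m = _complete_matrix()
        out, report = run_qc(m)
        assert report.n_units_after == report.n_units_before == 50
        assert report.removed_samples == []
        assert report.removed_units_missingness == []
        assert report.removed_units_bimodal == []
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_engineered_defects_each_caught_by_its_rule(self):
        out, report = run_qc(engineered_fixture())
        assert [s for s, _ in report.removed_samples] == ["s0"]
        assert [u for u, _ in report.removed_units_missingness] == ["B.u5"]
        assert [f.unit for f in report.removed_units_bimodal] == ["C.u3"]
        assert report.n_units_after == 48
        assert out.n_samples == 59

    def test_idempotent(self):
        clean, _ = run_qc(engineered_fixture())
        again, report = run_qc(clean)
        assert report.removed_samples == []
        assert report.removed_units_missingness == []
        assert report.removed_units_bimodal == []
        pd.testing.assert_frame_equal(again.data, clean.data)

    def test_survivor_order_preserved_and_bookkeeping_consistent(self):
        m = engineered_fixture()
        out, report = run_qc(m)
        survivors = [u for u in m.unit_ids if u not in {"B.u5", "C.u3"}]
        assert out.unit_ids == survivors
        report.validate()  # n_before - removed == n_after

    def test_sample_permutation_gives_same_removals(self):
        m = engineered_fixture()
        rng = np.random.default_rng(7)
        perm = list(rng.permutation(m.sample_ids))
        _, r1 = run_qc(m)
        _, r2 = run_qc(m.subset(samples=perm))
        assert {s for s, _ in r1.removed_samples} == {s for s, _ in r2.removed_samples}
        assert ({u for u, _ in r1.removed_units_missingness}
                == {u for u, _ in r2.removed_units_missingness})
        assert ({f.unit for f in r1.removed_units_bimodal}
                == {f.unit for f in r2.removed_units_bimodal})

    def test_fifty_units_in_thirty_nine_out_bookkeeping(self):
        """A fixture engineered to drop 11 units reproduces the 50 -> 39
        report arithmetic of a realistic cleaning run."""
        m = engineered_fixture()
        vals = m.data.to_numpy()
        extra = [1, 2, 10, 12, 20, 25, 30, 35, 40]  # 9 more high-missing units
        for j in extra:
            vals[1:22, j] = np.nan  # 21/59 = 35.6% among survivors
        m2 = make_matrix(vals, unit_ids=m.unit_ids)
        _, report = run_qc(m2)
        assert report.n_units_before == 50
        assert report.n_units_after == 39

    def test_control_units_excluded_up_front(self):
        m = _complete_matrix()
        out, report = run_qc(m, QCConfig(control_units=("A.u0", "A.u1")))
        assert report.n_units_before == 48
        assert "A.u0" not in out.unit_ids
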