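"""Resampling study: performance measures, losses, percentiles, n_eff."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import datsbr as d
from datsbr.cohort import CohortTable


def small_cohort(n_normal=40, n_disease=40, seed=5) -> CohortTable:
    import math
    from datsbr.cohort import CohortSpec, GroupSpec
    spec = CohortSpec(
        "small",
        GroupSpec("normal", n_normal, math.log(5.0), 0.28),
        GroupSpec("disease", n_disease, math.log(1.6), 0.36),
        seed=seed,
    )
    return d.sample_cohort(spec)


class TestPerformance:
    def test_clinical_sized_arithmetic(self):
        truth = np.r_[np.ones(186, bool), np.zeros(186, bool)]
        calls = np.r_[np.ones(150, bool), np.zeros(36, bool),   # disease rows
                      np.zeros(180, bool), np.ones(6, bool)]    # normal rows
        p = d.performance(calls, truth)
        assert p.sensitivity == pytest.approx(150 / 186)
        assert p.specificity == pytest.approx(180 / 186)
        assert p.accuracy == pytest.approx(330 / 372)

    def test_all_correct_and_all_negative(self):
        truth = np.array([True, True, False, False])
        assert d.performance(truth, truth) == d.PerformanceTriple(1.0, 1.0, 1.0)
        p = d.performance(np.zeros(4, bool), truth)
        assert (p.sensitivity, p.specificity) == (0.0, 1.0)

    def test_string_labels_accepted(self):
        p = d.performance([True, False], ["disease", "normal"])
        assert p.accuracy == 1.0

    def test_absent_group_rejected(self):
        with pytest.raises(ValueError, match="both groups"):
            d.performance([True, True], [True, True])

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=60))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_accuracy_identity(self, pairs):
        calls = np.array([c for c, _ in pairs])
        truth = np.array([t for _, t in pairs])
        if truth.all() or not truth.any():
            return
        p = d.performance(calls, truth)
        n_dis, n_norm = truth.sum(), (~truth).sum()
        expected = (p.sensitivity * n_dis + p.specificity * n_norm) / truth.size
        assert p.accuracy == pytest.approx(expected)


class TestHelpers:
    def test_relative_loss_arithmetic(self):
        assert d.relative_loss(0.95, 0.95) == 0.0
        assert d.relative_loss(0.95, 0.912) == pytest.approx(4.0)
        assert d.relative_loss(0.9, 0.95) < 0  # passed through unclipped
        with pytest.raises(ValueError, match="> 0"):
            d.relative_loss(0.0, 0.5)

    def test_percentile_5_linear_interpolation(self):
        assert d.percentile_5(np.arange(1, 101)) == pytest.approx(5.95)
        assert d.percentile_5([3.0, 3.0, 3.0]) == 3.0
        assert d.percentile_5([7.0]) == 7.0

    def test_effective_sample_size(self):
        assert d.effective_sample_size(20, 20) == 20.0
        assert d.effective_sample_size(1, 49) == pytest.approx(1.96)
        with pytest.raises(ValueError, match=">= 1"):
            d.effective_sample_size(0, 5)

    def test_neff_single_subject_bounded_and_increasing(self):
        vals = [d.effective_sample_size(1, n) for n in range(1, 500)]
        assert all(1.0 <= v < 2.0 for v in vals)
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestRunStudy:
    def test_reproducible_given_seed(self, clinical_cohort):
        grid = d.StudyGrid(sizes=(5, 10), repeats=200, seed=3)
        a = d.run_study(clinical_cohort, grid)
        b = d.run_study(clinical_cohort, grid)
        pd.testing.assert_frame_equal(a.per_size, b.per_size, check_exact=True)

    def test_full_group_database_reproduces_benchmark(self):
        co = small_cohort()
        grid = d.StudyGrid(sizes=(40,), repeats=25, seed=0)
        s = d.run_study(co, grid)
        row = s.loc(40)
        assert row["acc_mean"] == pytest.approx(s.benchmark.accuracy, abs=1e-15)
        assert row["acc_p5"] == pytest.approx(s.benchmark.accuracy, abs=1e-15)
        assert row["acc_sd"] < 1e-12
        assert row["mean_loss_pct"] == pytest.approx(0.0, abs=1e-12)
        assert row["max_loss_pct"] == pytest.approx(0.0, abs=1e-12)

    def test_accuracy_variability_decreases_with_size(self, clinical_cohort):
        grid = d.StudyGrid(sizes=(5, 15, 30, 50), repeats=2_000, seed=1)
        s = d.run_study(clinical_cohort, grid, method="aal")
        sd = s.per_size["acc_sd"].to_numpy()
        assert np.all(np.diff(sd) < 0)

    def test_p5_never_above_mean_on_defaults(self, clinical_cohort):
        s = d.run_study(clinical_cohort, d.StudyGrid(sizes=(5, 20), repeats=500, seed=2))
        for stem in ("acc", "sens", "spec"):
            assert (s.per_size[f"{stem}_p5"] <= s.per_size[f"{stem}_mean"]).all()

    def test_grid_larger_than_normal_group_rejected(self):
        co = small_cohort(n_normal=20)
        with pytest.raises(ValueError, match="exceeds"):
            d.run_study(co, d.StudyGrid(sizes=(5, 30), repeats=10, seed=0))

    def test_zero_variance_database_error_propagates(self):
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(8)],
            "group": ["normal"] * 4 + ["disease"] * 4,
            "sbr_aal": [2.0] * 4 + [0.5] * 4,
            "sbr_hv": [2.0] * 4 + [0.5] * 4,
        })
        co = CohortTable(df)
        with pytest.raises(ValueError, match="zero variance"):
            d.run_study(co, d.StudyGrid(sizes=(3,), repeats=5, seed=0))

    def test_excluding_database_members_changes_but_bounds_hold(self):
        co = small_cohort()
        grid = d.StudyGrid(sizes=(10,), repeats=300, seed=4)
        inc = d.run_study(co, grid)
        exc = d.run_study(co, grid, exclude_db_from_test=True)
        for col in ("acc_mean", "sens_mean", "spec_mean"):
            assert 0.0 <= exc.per_size[col].iloc[0] <= 1.0
        assert exc.per_size["acc_mean"].iloc[0] != inc.per_size["acc_mean"].iloc[0]

    def test_mean_loss_vanishes_at_full_group_size(self):
        co = small_cohort()
        s = d.run_study(co, d.StudyGrid(sizes=(20, 40), repeats=500, seed=6))
        assert abs(s.loc(40)["mean_loss_pct"]) < 1e-12
        # losses may be negative (a sampled database can beat the benchmark)
        # but the 5th-percentile-based loss can never undercut the mean loss
        assert s.loc(20)["max_loss_pct"] >= s.loc(20)["mean_loss_pct"]
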