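"""Preprocessing chain: normalization, Dixon filter, autoscaling, imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemotyper import (
    TableState,
    ValidationError,
    dixon_critical_value,
    dixon_filter,
    knn_impute,
    log_autoscale,
    median_normalize,
    preprocess_pipeline,
)
from chemotyper.preprocess import PreprocessConfig, _dixon_q

from conftest import make_metadata, make_table


class TestMedianNormalize:
    def test_hand_example(self):
        table = make_table([[2.0, 4.0, 8.0]])
        out, factors = median_normalize(table)
        np.testing.assert_allclose(out.values.to_numpy()[0], [0.5, 1.0, 2.0])
        assert factors["s1"] == 4.0
        assert out.state is TableState.NORMALIZED

    def test_constant_sample_maps_to_ones(self):
        out, factors = median_normalize(make_table([[7.0, 7.0, 7.0]]))
        np.testing.assert_allclose(out.values.to_numpy()[0], [1, 1, 1])

    def test_idempotent(self):
        table = make_table([[2.0, 4.0, 8.0], [1.0, 5.0, 9.0]])
        once, _ = median_normalize(table)
        twice, factors2 = median_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy()
        )
        assert all(abs(f - 1) < 1e-12 for f in factors2.values())

    def test_all_missing_sample_errors(self):
        table = make_table([[np.nan, np.nan]])
        with pytest.raises(ValidationError, match="s1"):
            median_normalize(table)

    def test_zero_median_errors(self):
        with pytest.raises(ValidationError, match="median 0"):
            median_normalize(make_table([[0.0, 0.0, 5.0]]))

    @settings(max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=1e6),
            min_size=3, max_size=12, unique=True,
        )
    )
    def test_preserves_within_sample_rank_order(self, values):
        table = make_table([values])
        out, _ = median_normalize(table)
        orig = np.argsort(table.values.to_numpy()[0])
        new = np.argsort(out.values.to_numpy()[0])
        assert (orig == new).all()


class TestDixonFilter:
    def test_hand_q_statistic(self):
        q, idx = _dixon_q(np.array([2.1, 2.2, 2.3, 5.0]))
        assert q == pytest.approx(2.7 / 2.9, abs=1e-12)
        assert idx == 3

    def test_outlier_removed_when_q_exceeds_critical(self):
        table = make_table([[2.1], [2.2], [2.3], [5.0]])
        meta = make_metadata(["s1", "s2", "s3", "s4"])
        out, report = dixon_filter(table, meta)
        assert len(report.outliers_removed) == 1
        mid, sid, value, q, crit = report.outliers_removed[0]
        assert (mid, sid, value) == ("M1", "s4", 5.0)
        assert q > crit == 0.829
        assert np.isnan(out.values.loc["s4", "M1"])

    def test_no_removal_below_critical(self):
        table = make_table([[2.1], [2.2], [2.3], [2.6]])
        meta = make_metadata(["s1", "s2", "s3", "s4"])
        _, report = dixon_filter(table, meta)
        assert report.outliers_removed == []

    def test_constant_group_never_tested(self):
        table = make_table([[3.0], [3.0], [3.0], [3.0]])
        meta = make_metadata(["s1", "s2", "s3", "s4"])
        _, report = dixon_filter(table, meta)
        assert report.outliers_removed == []

    def test_small_groups_skipped_with_warning(self):
        table = make_table([[1.0], [100.0]])
        meta = make_metadata(["s1", "s2"])
        with pytest.warns(UserWarning, match="fewer than 3"):
            _, report = dixon_filter(table, meta)
        assert report.outliers_removed == []

    def test_alpha_validation(self):
        table = make_table([[1.0], [2.0], [3.0]])
        meta = make_metadata(["s1", "s2", "s3"])
        with pytest.raises(ValidationError):
            dixon_filter(table, meta, alpha=1.5)

    def test_at_most_one_removal_per_metabolite_group(self):
        # two extremes, only the larger-gap one may go
        table = make_table([[0.01], [2.0], [2.1], [2.2], [60.0]])
        meta = make_metadata([f"s{i}" for i in range(1, 6)])
        _, report = dixon_filter(table, meta)
        assert len(report.outliers_removed) <= 1

    def test_decisions_match_hand_oracle_on_constructed_groups(self):
        """Dixon decisions agree with a hand recomputation on 24 groups."""
        rng = np.random.default_rng(42)
        for trial in range(24):
            n = int(rng.integers(3, 9))
            base = rng.lognormal(1.0, 0.2, size=n)
            if trial % 2 == 0:
                base[rng.integers(n)] *= 12.0
            table = make_table(base[:, None])
            meta = make_metadata(table.sample_ids)
            _, report = dixon_filter(table, meta)
            # independent oracle: sort, gap/range on the wider end
            x = np.sort(base)
            gap_low, gap_high = x[1] - x[0], x[-1] - x[-2]
            q = max(gap_low, gap_high) / (x[-1] - x[0])
            expect_removal = q > dixon_critical_value(n, 0.05)
            assert bool(report.outliers_removed) == expect_removal
            if expect_removal:
                removed_value = report.outliers_removed[0][2]
                expected = x[-1] if gap_high >= gap_low else x[0]
                assert removed_value == pytest.approx(expected)


class TestLogAutoscale:
    def test_hand_example(self):
        table = make_table([[1.0], [np.e**2]])
        out = log_autoscale(table)
        np.testing.assert_allclose(
            out.values.to_numpy()[:, 0], [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12
        )
        assert out.state is TableState.LOG_SCALED

    def test_constant_column_scales_to_zeros(self):
        out = log_autoscale(make_table([[5.0], [5.0], [5.0]]))
        np.testing.assert_allclose(out.values.to_numpy(), 0.0)

    def test_columns_standardised(self):
        rng = np.random.default_rng(3)
        out = log_autoscale(make_table(rng.lognormal(2, 1, (20, 6))))
        arr = out.values.to_numpy()
        np.testing.assert_allclose(arr.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(arr.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_non_positive_value_names_cell(self):
        with pytest.raises(ValidationError, match="M2"):
            log_autoscale(make_table([[1.0, 0.0], [2.0, 3.0]]))


def brute_force_knn(arr, i, j, k):
    """Independent oracle for the documented row-KNN scheme."""
    target = arr[:, j]
    best = []
    for m in range(arr.shape[1]):
        if m == j or np.isnan(arr[i, m]):
            continue
        overlap = ~np.isnan(target) & ~np.isnan(arr[:, m])
        if not overlap.any():
            continue
        d = np.sqrt(np.mean((target[overlap] - arr[overlap, m]) ** 2))
        best.append((d, m))
    best.sort(key=lambda t: t[0])
    donors = [m for _, m in best[:k]]
    return float(np.mean(arr[i, donors])) if donors else np.nan


class TestKnnImpute:
    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(5)
        table = make_table(rng.standard_normal((6, 5)), state=TableState.LOG_SCALED)
        meta = make_metadata(table.sample_ids)
        out, report = knn_impute(table, meta)
        np.testing.assert_array_equal(out.values.to_numpy(), table.values.to_numpy())
        assert report.imputed_cells == []
        assert out.state is TableState.IMPUTED

    def test_duplicated_row_twin_fills_missing(self):
        values = np.array(
            [[1.0, 1.0, 0.5], [2.0, 2.0, -1.0], [0.3, 0.3, 2.0], [1.7, np.nan, 0.1]]
        )
        table = make_table(values, state=TableState.LOG_SCALED)
        meta = make_metadata(table.sample_ids, replicate=[1, 2, 3, 4])
        out, report = knn_impute(table, meta, k=1)
        # M1 is an exact twin of M2 on observed entries
        assert out.values.loc["s4", "M2"] == pytest.approx(1.7)

    def test_matches_brute_force_neighbour_search(self):
        """Row-KNN equals exhaustive distance computation (up to 20x12)."""
        rng = np.random.default_rng(11)
        for trial in range(8):
            n, m = int(rng.integers(5, 13)), int(rng.integers(6, 21))
            arr = rng.standard_normal((n, m))
            holes = rng.random((n, m)) < 0.08
            holes[:, 0] = False  # keep one complete metabolite
            arr[holes] = np.nan
            k = int(rng.integers(1, 6))
            table = make_table(arr, state=TableState.LOG_SCALED)
            meta = make_metadata(table.sample_ids)
            out, report = knn_impute(table, meta, k=k)
            for mid, sid, value in report.imputed_cells:
                i = table.sample_ids.index(sid)
                j = table.metabolite_ids.index(mid)
                assert value == pytest.approx(brute_force_knn(arr, i, j, k))

    def test_observed_values_never_altered(self):
        rng = np.random.default_rng(13)
        arr = rng.standard_normal((8, 10))
        arr[rng.random((8, 10)) < 0.1] = np.nan
        table = make_table(arr, state=TableState.LOG_SCALED)
        meta = make_metadata(table.sample_ids)
        out, _ = knn_impute(table, meta, k=3)
        observed = ~np.isnan(arr)
        np.testing.assert_array_equal(
            out.values.to_numpy()[observed], arr[observed]
        )

    def test_group_wide_absence_left_missing(self):
        arr = np.array(
            [[np.nan, 1.0, 2.0], [np.nan, 1.1, 2.2],
             [3.0, 1.0, 2.1], [3.1, 0.9, 2.0]]
        )
        table = make_table(arr, state=TableState.LOG_SCALED)
        meta = make_metadata(
            table.sample_ids, time_das=[3, 3, 5, 5], replicate=[1, 2, 1, 2]
        )
        out, report = knn_impute(table, meta, k=2)
        assert np.isnan(out.values.loc["s1", "M1"])
        assert np.isnan(out.values.loc["s2", "M1"])
        assert any(m == "M1" for m, _ in report.left_missing)

    def test_imputed_value_within_donor_range(self):
        rng = np.random.default_rng(17)
        arr = rng.standard_normal((10, 12))
        arr[2, 4] = np.nan
        table = make_table(arr, state=TableState.LOG_SCALED)
        meta = make_metadata(table.sample_ids)
        out, report = knn_impute(table, meta, k=5)
        (mid, sid, value), = report.imputed_cells
        row = arr[2, :]
        assert np.nanmin(row) <= value <= np.nanmax(row)


class TestPipeline:
    def test_clean_table_passes_through(self):
        rng = np.random.default_rng(19)
        table = make_table(rng.lognormal(3, 0.05, (8, 6)))
        meta = make_metadata(table.sample_ids, replicate=list(range(1, 9)))
        out, report = preprocess_pipeline(table, meta)
        assert out.state is TableState.IMPUTED
        assert report.outliers_removed == []
        assert report.imputed_cells == []

    def test_planted_outlier_reported_and_imputed(self):
        rng = np.random.default_rng(20)
        values = rng.lognormal(3, 0.05, (4, 6))
        values[2, 3] *= 40
        table = make_table(values)
        meta = make_metadata(table.sample_ids)
        out, report = preprocess_pipeline(table, meta)
        assert [(m, s) for m, s, *_ in report.outliers_removed] == [("M4", "s3")]
        assert [(m, s) for m, s, _ in report.imputed_cells] == [("M4", "s3")]

    def test_deterministic(self, study):
        again, _ = preprocess_pipeline(study.table, study.metadata)
        np.testing.assert_array_equal(
            again.values.to_numpy(), study.processed.values.to_numpy()
        )

    def test_impute_before_scale_mode_runs(self, study):
        cfg = PreprocessConfig(impute_before_scale=True)
        out, _ = preprocess_pipeline(study.table, study.metadata, cfg)
        assert out.state is TableState.IMPUTED

    def test_report_serialises(self, study):
        frame = study.report.to_frame()
        assert set(frame["action"]) <= {"outlier_removed", "imputed", "left_missing"}
        assert len(frame) >= len(study.report.outliers_removed)


class TestGeneratorRecovery:
    def test_outlier_recall_and_false_positive_rate(self, study_bank):
        """Planted 30x spikes are recovered; clean groups stay below alpha+2%."""
        recalls, fprs = [], []
        for study in study_bank.values():
            planted = set(study.truth.outlier_cells)
            removed = {(s, m) for m, s, *_ in study.report.outliers_removed}
            recalls.append(len(planted & removed) / len(planted))
            n_groups = study.table.n_metabolites * 12
            fprs.append(len(removed - planted) / n_groups)
        assert np.mean(recalls) >= 0.9
        assert np.mean(fprs) <= 0.05 + 0.02
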