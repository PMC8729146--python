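"""Importance ranking, threshold filtering, mode imputation, sequences."""

import numpy as np
import pandas as pd
import pytest

from toastnet import (
    CohortSpec,
    CohortTable,
    ImportanceReport,
    compute_importance,
    filter_and_rank,
    generate_cohort,
    impute_mode,
    to_sequence,
)


def make_table(columns: dict, labels) -> CohortTable:
    data = pd.DataFrame(columns)
    return CohortTable(
        data=data,
        labels=np.asarray(labels, dtype=int),
        kinds={c: "continuous" for c in data.columns},
    )


class TestImportance:
    def test_informative_features_outrank_noise(self, small_cohort):
        (imputed,) = impute_mode(small_cohort)
        report = compute_importance(imputed, seed=0)
        informative = set(small_cohort.informative)
        inf = [v for k, v in report.importances.items() if k in informative]
        noise = [v for k, v in report.importances.items() if k not in informative]
        assert np.mean(inf) > np.mean(noise)

    def test_importances_normalized_and_deterministic(self, small_cohort):
        (imputed,) = impute_mode(small_cohort)
        a = compute_importance(imputed, seed=5)
        b = compute_importance(imputed, seed=5)
        assert a.importances == b.importances
        assert np.isclose(sum(a.importances.values()), 1.0)
        assert all(v >= 0 for v in a.importances.values())

    def test_constant_feature_gets_zero(self, rng):
        table = make_table(
            {
                "num_000": rng.normal(size=200),
                "num_001": np.ones(200),
                "num_002": rng.normal(size=200) + np.repeat([0, 2], 100),
            },
            np.repeat([0, 1], 100),
        )
        report = compute_importance(table, seed=0)
        assert report.importances["num_001"] == 0.0

    def test_single_class_labels_error(self, rng):
        table = make_table({"num_000": rng.normal(size=50)}, np.zeros(50))
        with pytest.raises(ValueError):
            compute_importance(table, seed=0)

    def test_permuted_labels_kill_signal(self):
        """Label-permutation null: with shuffled labels no feature should
        concentrate importance beyond the permutation distribution."""
        spec = CohortSpec(
            n_patients=300,
            class_counts=(150, 30, 60, 25, 35),
            n_features=15,
            n_informative=6,
            effect_size=1.5,
            missing_rate=0.0,
            seed=11,
        )
        table = generate_cohort(spec)
        rng = np.random.default_rng(0)
        null_max = []
        for i in range(20):
            perm = CohortTable(
                table.data, rng.permutation(table.labels), dict(table.kinds)
            )
            rep = compute_importance(perm, seed=i)
            null_max.append(max(rep.importances.values()))
        threshold = np.quantile(null_max, 0.95)
        # true labels concentrate importance far beyond the null
        true_rep = compute_importance(table, seed=0)
        assert max(true_rep.importances.values()) > threshold
        # a zero-effect cohort behaves like the null
        flat = generate_cohort(
            CohortSpec(**{**spec.__dict__, "effect_size": 0.0})
        )
        flat_rep = compute_importance(flat, seed=0)
        assert max(flat_rep.importances.values()) <= np.max(null_max) * 1.5


class TestFilterAndRank:
    def test_threshold_is_inclusive_drop(self):
        report = ImportanceReport({"f1": 0.2, "f2": 0.005, "f3": 0.0})
        kept, dropped = filter_and_rank(report, 0.005)
        assert kept == ["f1"]
        assert dropped == ["f2", "f3"]

    def test_stable_tie_break_keeps_column_order(self):
        report = ImportanceReport({"a": 0.25, "b": 0.25, "c": 0.25, "d": 0.25})
        kept, dropped = filter_and_rank(report, 0.005)
        assert kept == ["a", "b", "c", "d"]
        assert dropped == []

    def test_29_of_122_subthreshold_leaves_93(self):
        values = [0.005 if i < 29 else 0.005 + (i - 28) * 1e-4 for i in range(122)]
        total = sum(values)
        report = ImportanceReport(
            {f"f{i:03d}": v / total for i, v in enumerate(values)}
        )
        kept, dropped = filter_and_rank(report, 0.005 / total)
        assert len(kept) == 93
        assert len(dropped) == 29

    def test_zero_threshold_keeps_positive_importance(self):
        report = ImportanceReport({"a": 0.6, "b": 0.4, "c": 0.0})
        kept, dropped = filter_and_rank(report, 0.0)
        assert kept == ["a", "b"]
        assert dropped == ["c"]

    def test_all_dropped_is_diagnosed(self):
        report = ImportanceReport({"a": 0.0, "b": 0.0})
        with pytest.raises(ValueError, match="threshold"):
            filter_and_rank(report, 0.005)


class TestImputeMode:
    def test_fills_with_mode(self):
        table = make_table({"x": [1.0, 1.0, 2.0, np.nan]}, [0, 0, 1, 1])
        (out,) = impute_mode(table)
        assert out.data["x"].tolist() == [1.0, 1.0, 2.0, 1.0]

    def test_bimodal_tie_takes_smallest(self):
        table = make_table({"x": [3.0, 3.0, 7.0, 7.0, np.nan]}, [0, 0, 1, 1, 0])
        (out,) = impute_mode(table)
        assert out.data["x"].iloc[-1] == 3.0

    def test_no_missing_is_identity_and_idempotent(self, small_cohort):
        (once,) = impute_mode(small_cohort)
        (twice,) = impute_mode(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert not once.data.isna().any().any()

    def test_mode_fitted_on_train_applied_to_test(self):
        train = make_table({"x": [5.0, 5.0, 9.0]}, [0, 0, 1])
        test = make_table({"x": [np.nan, 1.0]}, [0, 1])
        _, test_out = impute_mode(train, [test])
        assert test_out.data["x"].tolist() == [5.0, 1.0]

    def test_entirely_missing_feature_named_in_error(self):
        train = make_table({"bad": [np.nan, np.nan]}, [0, 1])
        with pytest.raises(ValueError, match="bad"):
            impute_mode(train)


class TestToSequence:
    def test_identity_and_reversed_ordering(self, rng):
        cols = {f"f{i}": rng.normal(size=5) for i in range(4)}
        table = make_table(cols, np.zeros(5))
        names = list(cols)
        seq = to_sequence(table, names)
        np.testing.assert_array_equal(seq.values, table.data.to_numpy())
        rev = to_sequence(table, names[::-1])
        np.testing.assert_array_equal(rev.values, table.data.to_numpy()[:, ::-1])

    def test_round_trip_through_inverse_permutation(self, rng):
        cols = {f"f{i}": rng.normal(size=6) for i in range(5)}
        table = make_table(cols, np.zeros(6))
        ordering = list(rng.permutation(list(cols)))
        seq = to_sequence(table, ordering)
        inverse = [ordering.index(name) for name in cols]
        np.testing.assert_array_equal(seq.values[:, inverse], table.data.to_numpy())

    def test_no_scaling_invariant(self, small_cohort):
        """Every sequence cell is a raw table value, untouched."""
        (imputed,) = impute_mode(small_cohort)
        ordering = list(imputed.feature_names[:10])
        seq = to_sequence(imputed, ordering)
        source = imputed.data[ordering].to_numpy()
        np.testing.assert_array_equal(seq.values, source)

    def test_unknown_feature_errors(self, small_cohort):
        (imputed,) = impute_mode(small_cohort)
        with pytest.raises(KeyError):
            to_sequence(imputed, ["nonexistent"])
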