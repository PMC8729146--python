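"""Metrics, paired deltas, cross-validation, and the experiment grid."""

import numpy as np
import pandas as pd
import pytest

from toastnet import (
    CohortSpec,
    LossConfig,
    NetworkSpec,
    build_network,
    compute_metrics,
    cross_validate,
    generate_cohort,
    report_delta,
    run_experiment,
)
from conftest import random_proba


def onehot(y, k=5):
    return np.eye(k)[y]


class TestComputeMetrics:
    def test_perfect_prediction(self, rng):
        y = rng.integers(0, 5, 100)
        m = compute_metrics(y, onehot(y) * 0.95 + 0.01)
        assert m.accuracy == 1.0
        assert m.precision == 1.0
        assert m.recall == 1.0
        assert m.f1 == 1.0
        assert np.trace(m.confusion) == 100

    def test_two_class_confusion_arithmetic(self):
        """TP=3, FP=1, FN=1, TN=5 gives precision = recall = F1 = 0.75."""
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 1])
        proba = np.where(y_pred[:, None] == np.arange(2), 0.9, 0.1)
        m = compute_metrics(y_true, proba)
        cls = m.per_class.loc["class_1"]
        assert cls.precision == pytest.approx(0.75)
        assert cls.recall == pytest.approx(0.75)
        assert cls.f1 == pytest.approx(0.75)

    def test_weighted_recall_equals_accuracy_identity(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 5, n)
            m = compute_metrics(y, random_proba(rng, n))
            assert m.recall == pytest.approx(m.accuracy, abs=1e-12)

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0, 1]), np.array([[0.5, 0.7], [0.2, 0.8]]))

    def test_absent_class_warns_and_excludes(self, rng):
        y = rng.integers(0, 3, 60)  # classes 3, 4 never occur
        with pytest.warns(UserWarning, match="absent"):
            m = compute_metrics(y, random_proba(rng, 60))
        assert len(m.per_class) == 3

    def test_confusion_total_conservation(self, rng):
        y = rng.integers(0, 5, 123)
        m = compute_metrics(y, random_proba(rng, 123))
        assert m.confusion.sum() == 123


class TestReportDelta:
    def _report(self, per_class_precision, recall_first):
        per_class = pd.DataFrame(
            {
                "precision": per_class_precision,
                "recall": [recall_first, 0.5, 0.5, 0.5, 0.5],
                "f1": [0.5] * 5,
                "support": [10] * 5,
            },
            index=["LAA", "CE", "SAO", "OC", "UND"],
        )
        return type(
            "R",
            (),
            {
                "accuracy": 0.6, "auc": 0.7, "precision": 0.6, "recall": 0.6,
                "f1": 0.5, "per_class": per_class,
            },
        )()

    def test_published_sao_precision_delta(self):
        a = self._report([0.5960, 0.6220, 0.3966, 0.2917, 0.3067], 0.8774)
        b = self._report([0.6559, 0.7208, 0.5690, 0.4785, 0.3943], 0.7552)
        delta = report_delta(a, b)
        assert delta["per_class"].loc["SAO", "precision"] == pytest.approx(0.1724)
        assert delta["per_class"].loc["LAA", "recall"] == pytest.approx(-0.1222)

    def test_identical_reports_give_zero_deltas(self):
        a = self._report([0.5] * 5, 0.5)
        delta = report_delta(a, a)
        assert all(v == 0 for v in delta["overall"].values())
        assert (delta["per_class"].to_numpy() == 0).all()

    def test_class_set_mismatch_rejected(self):
        a = self._report([0.5] * 5, 0.5)
        b = self._report([0.5] * 5, 0.5)
        b.per_class = b.per_class.drop(index="OC")
        with pytest.raises(ValueError):
            report_delta(a, b)


def tiny_factory(L):
    return build_network(
        NetworkSpec(
            variant="V2", sequence_length=L, conv1=(4, 3, 1), conv2=(4, 3, 2),
            pool=(2, 2), head_width=8, seed=0,
        )
    )


@pytest.fixture(scope="module")
def tiny_cohort():
    return generate_cohort(
        CohortSpec(
            n_patients=150,
            class_counts=(60, 20, 30, 15, 25),
            n_features=12,
            n_informative=6,
            effect_size=2.0,
            missing_rate=0.01,
            seed=5,
        )
    )


class TestCrossValidate:
    def test_fold_partition_laws(self, tiny_cohort):
        reports, mean = cross_validate(
            tiny_factory, tiny_cohort, k=3, seed=0, epochs=2
        )
        sizes = [r.n_samples for r in reports]
        assert sum(sizes) == tiny_cohort.n_patients
        assert max(sizes) - min(sizes) <= 1
        assert mean.confusion.sum() == tiny_cohort.n_patients

    def test_small_class_under_stratification_suggests_fallback(self, tiny_cohort):
        with pytest.raises(ValueError, match="stratified=False"):
            cross_validate(tiny_factory, tiny_cohort, k=16, seed=0, epochs=1)

    def test_leave_one_out_on_tiny_table(self):
        cohort = generate_cohort(
            CohortSpec(
                n_patients=12, class_counts=(4, 2, 2, 2, 2), n_features=6,
                n_informative=3, effect_size=1.0, missing_rate=0.0, seed=1,
            )
        )
        reports, _ = cross_validate(
            tiny_factory, cohort, k=12, stratified=False, seed=0, epochs=1
        )
        assert len(reports) == 12
        assert all(r.n_samples == 1 for r in reports)

    def test_mean_accuracy_beats_majority_on_separable_cohort(self, tiny_cohort):
        reports, mean = cross_validate(
            tiny_factory, tiny_cohort, k=3, seed=0, epochs=40
        )
        majority = max(np.bincount(tiny_cohort.labels)) / tiny_cohort.n_patients
        assert mean.accuracy > majority


class TestRunExperiment:
    def test_grid_size_and_outputs(self, tiny_cohort, tmp_path):
        config = {
            "variants": ["V1", "V2"],
            "losses": ["kl_focal"],
            "strategies": ["none"],
            "epochs": 2,
            "seed": 0,
        }
        results, frame = run_experiment(config, tiny_cohort, tmp_path)
        assert len(results) == 2
        assert len(frame) == 2
        assert (tmp_path / "grid.csv").exists()
        assert (tmp_path / "grid.json").exists()

    def test_unknown_names_fail_before_training(self, tiny_cohort):
        with pytest.raises(ValueError, match="variant"):
            run_experiment({"variants": ["V5"]}, tiny_cohort)
        with pytest.raises(ValueError, match="loss"):
            run_experiment({"losses": ["hinge"]}, tiny_cohort)
        with pytest.raises(ValueError, match="strategy"):
            run_experiment({"strategies": ["committee"]}, tiny_cohort)

    def test_empty_grid_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="empty"):
            run_experiment({"variants": []}, tiny_cohort)
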