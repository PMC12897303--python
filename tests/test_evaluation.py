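"""Subject-wise splitting, classifier behavior, and metric aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegrisk.evaluation import (
    ClassifierConfig,
    SplitPlan,
    compute_metrics,
    subject_wise_split,
    train_and_predict,
)
from eegrisk.tasks import TaskDataset


def _blob_dataset(n_subjects=10, per_subject=20, n_features=5, sep=8.0, seed=0):
    """Two well-separated Gaussian blobs, half the subjects in each class."""
    rng = np.random.default_rng(seed)
    X, y, subj = [], [], []
    for i in range(n_subjects):
        label = "pos" if i % 2 == 0 else "neg"
        center = sep if label == "pos" else -sep
        X.append(center + rng.standard_normal((per_subject, n_features)))
        y += [label] * per_subject
        subj += [f"s{i}"] * per_subject
    return TaskDataset(
        task_id=1, X=np.vstack(X), y=np.array(y), subjects=np.array(subj),
        source_labels=np.array(y),
    )


class TestSplit:
    def test_twenty_subjects_fraction_point_two(self):
        ds = _blob_dataset(n_subjects=20)
        plan = subject_wise_split(ds, 0.2, seed=0)
        assert len(plan.test_subjects) == 4
        assert len(plan.train_subjects) == 16

    def test_partitions_are_disjoint(self):
        ds = _blob_dataset()
        plan = subject_wise_split(ds, 0.3, seed=1)
        assert not set(plan.train_subjects) & set(plan.test_subjects)

    def test_rare_class_in_two_subjects_lands_on_both_sides(self):
        # every subject carries pos and neg; "rare" only in s0 and s1
        rng = np.random.default_rng(0)
        X, y, subj = [], [], []
        for i in range(10):
            X.append(rng.standard_normal((10, 3)))
            y += ["pos"] * 5 + ["neg"] * 5
            subj += [f"s{i}"] * 10
        y = np.array(y)
        subj = np.array(subj)
        y[np.isin(subj, ["s0", "s1"]) & (y == "pos")] = "rare"
        ds = TaskDataset(1, np.vstack(X), y, subj, y)
        plan = subject_wise_split(ds, 0.2, seed=3)
        test, train = set(plan.test_subjects), set(plan.train_subjects)
        assert len({"s0", "s1"} & test) == 1
        assert len({"s0", "s1"} & train) == 1

    def test_single_carrier_class_unsatisfiable(self):
        ds = _blob_dataset(n_subjects=6)
        y = ds.y.copy()
        y[ds.subjects == "s0"] = "orphan"
        ds = TaskDataset(1, ds.X, y, ds.subjects, y)
        with pytest.raises(ValueError, match="only 1 subject"):
            subject_wise_split(ds, 0.2, seed=0)

    def test_overlapping_plan_construction_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan(("a", "b"), ("b", "c"), seed=0, task_id=1)

    def test_disjoint_across_many_seeds(self):
        ds = _blob_dataset(n_subjects=12)
        for seed in range(50):
            plan = subject_wise_split(ds, 0.25, seed=seed)
            assert not set(plan.train_subjects) & set(plan.test_subjects)


class TestClassifiers:
    @pytest.mark.parametrize("model", ["svm", "rf", "knn"])
    def test_separable_blobs_are_perfectly_classified(self, model):
        ds = _blob_dataset()
        plan = subject_wise_split(ds, 0.2, seed=0)
        pred = train_and_predict(ClassifierConfig(model=model, seed=0), plan, ds)
        te = np.isin(ds.subjects, plan.test_subjects)
        assert (pred == ds.y[te]).all()

    def test_rf_same_seed_identical_predictions(self):
        ds = _blob_dataset(sep=0.5, seed=4)  # overlapping blobs, non-trivial fit
        plan = subject_wise_split(ds, 0.2, seed=0)
        cfg = ClassifierConfig(model="rf", seed=9, rf_n_trees=50)
        a = train_and_predict(cfg, plan, ds)
        b = train_and_predict(cfg, plan, ds)
        np.testing.assert_array_equal(a, b)

    def test_knn_returns_label_of_duplicated_train_point(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [0.1, 0.1], [4.9, 5.1],
                      [0.0, 0.0], [9.0, 9.0]])
        y = np.array(["a", "b", "a", "b", "a", "b"])
        subj = np.array(["t1", "t1", "t2", "t2", "q", "q"])
        ds = TaskDataset(1, X, y, subj, y)
        plan = SplitPlan(("t1", "t2"), ("q",), seed=0, task_id=1)
        pred = train_and_predict(ClassifierConfig(model="knn"), plan, ds)
        assert pred[0] == "a"  # test row duplicates train row [0, 0]

    def test_single_class_training_rejected(self):
        ds = _blob_dataset(n_subjects=4)
        plan = SplitPlan(("s0", "s2"), ("s1", "s3"), seed=0, task_id=1)  # only "pos"
        with pytest.raises(ValueError, match="single class"):
            train_and_predict(ClassifierConfig(model="svm"), plan, ds)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            ClassifierConfig(model="mlp").build()


class TestMetrics:
    def test_perfect_predictions_are_all_hundred(self):
        y = np.array(["A", "B", "B", "C"])
        rep = compute_metrics(y, y)
        for name in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
            assert getattr(rep, name) == pytest.approx(100.0)

    def test_hand_computed_binary_confusion(self):
        # TP=8 FN=2 / FP=1 TN=9 on a 10/10 split
        y_true = np.array(["pos"] * 10 + ["neg"] * 10)
        y_pred = np.array(["pos"] * 8 + ["neg"] * 2 + ["pos"] * 1 + ["neg"] * 9)
        rep = compute_metrics(y_true, y_pred)
        assert rep.accuracy == pytest.approx(85.00)
        assert rep.sensitivity == pytest.approx(85.00)
        assert rep.specificity == pytest.approx(85.00)
        assert rep.precision == pytest.approx(85.3535, abs=0.01)

    def test_confusion_rows_sum_to_true_counts(self):
        y_true = np.array(["A", "A", "B", "C", "C", "C"])
        y_pred = np.array(["A", "B", "B", "C", "A", "C"])
        rep = compute_metrics(y_true, y_pred)
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), [2, 1, 3])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.sampled_from("ABC"), st.sampled_from("ABC")),
            min_size=1, max_size=60,
        )
    )
    def test_weighted_sensitivity_always_equals_accuracy(self, data):
        y_true = np.array([a for a, _ in data])
        y_pred = np.array([b for _, b in data])
        labels = sorted(set(y_true) | set(y_pred))
        rep = compute_metrics(y_true, y_pred, labels=labels)
        assert rep.sensitivity == pytest.approx(rep.accuracy, abs=1e-9)

    def test_prediction_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            compute_metrics(np.array(["A", "B"]), np.array(["A", "Z"]),
                            labels=["A", "B"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            compute_metrics(np.array(["A"]), np.array(["A", "B"]))
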