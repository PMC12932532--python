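"""Patient-level splits, class weighting, training schedule, metrics and
event-level evaluation."""

import math
import warnings

import numpy as np
import pytest
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from apneaformer.config import TrainConfig
from apneaformer.model import ApneaTransformerClassifier
from apneaformer.train_eval import (
    ConfusionCounts,
    aggregate_events,
    class_weights,
    compute_metrics,
    confusion,
    make_folds,
    match_events,
    split_patients,
    train,
)
from apneaformer.preprocess import project_event_labels

SUBJECTS = [f"S{i:02d}" for i in range(1, 31)]


class TestSplits:
    def test_80_20_subject_split(self):
        plan = split_patients(SUBJECTS, seed=1)
        assert len(plan.dev_subjects) == 24
        assert len(plan.test_subjects) == 6
        assert not set(plan.dev_subjects) & set(plan.test_subjects)

    def test_seed_determinism(self):
        a = split_patients(SUBJECTS, seed=42)
        b = split_patients(SUBJECTS, seed=42)
        assert a.dev_subjects == b.dev_subjects
        assert a.test_subjects == b.test_subjects

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            split_patients(["a", "b"], seed=0)

    def test_nested_folds_partition_dev_set(self):
        plan = split_patients(SUBJECTS, seed=3)
        folds = make_folds(plan.dev_subjects, k=5, seed=3)
        flat = [s for fold in folds for s in fold]
        assert sorted(flat) == sorted(plan.dev_subjects)
        assert len(flat) == len(set(flat))  # no subject validates twice

    def test_equal_folds_when_divisible(self):
        folds = make_folds([f"P{i}" for i in range(25)], k=5, seed=0)
        assert [len(f) for f in folds] == [5] * 5

    def test_paper_literal_23_7(self):
        folds = make_folds(SUBJECTS, k=5, seed=0, mode="paper_literal")
        for fold in folds:
            assert len(fold) == 7
            assert len(set(SUBJECTS) - set(fold)) == 23

    def test_no_leakage_within_each_fold(self):
        plan = split_patients(SUBJECTS, seed=7)
        plan.folds = make_folds(plan.dev_subjects, k=5, seed=7)
        for k in range(5):
            train_s, val_s = plan.fold_split(k)
            assert not set(train_s) & set(val_s)
            assert not set(val_s) & set(plan.test_subjects)

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            make_folds(SUBJECTS, k=1)


class TestClassWeights:
    def test_balanced_classes_unit_weights(self):
        w = class_weights(np.array([0, 1, 0, 1]))
        assert w == {"weight_pos": 1.0, "weight_neg": 1.0}

    def test_skewed_fraction(self):
        y = np.concatenate([np.ones(145), np.zeros(855)])
        w = class_weights(y)
        assert w["weight_pos"] == pytest.approx(3.448, abs=0.001)
        assert w["weight_neg"] == pytest.approx(0.585, abs=0.001)

    def test_weighted_masses_equal(self, rng):
        y = (rng.random(997) < 0.23).astype(int)
        w = class_weights(y)
        assert math.isclose(w["weight_pos"] * y.sum(),
                            w["weight_neg"] * (len(y) - y.sum()),
                            rel_tol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(np.ones(10))


class TestTraining:
    def test_lr_schedule_values(self):
        clf = ApneaTransformerClassifier()
        assert clf.learning_rate_at(5) == 1e-3
        assert clf.learning_rate_at(10) == 1e-3
        assert clf.learning_rate_at(11) == pytest.approx(9e-4)
        assert clf.learning_rate_at(12) == pytest.approx(8.1e-4)
        assert clf.learning_rate_at(200) == 1e-4  # floor

    def test_zero_epochs_returns_initialized_model(self, rng):
        clf = ApneaTransformerClassifier(num_blocks=1, num_heads=1,
                                         head_size=4, epochs=0,
                                         class_weight=None, random_state=0)
        X = rng.normal(size=(4, 30, 1)).astype(np.float32)
        y = np.zeros((4, 30), dtype=np.int8)
        clf.fit(X, y)
        assert clf.history_ == {"loss": [], "lr": []}
        assert clf.predict_proba(X).shape == (4, 30)

    def test_single_class_with_balancing_refused(self, rng):
        clf = ApneaTransformerClassifier(num_blocks=1, num_heads=1,
                                         head_size=4, epochs=1,
                                         class_weight="balanced")
        X = rng.normal(size=(4, 30, 1)).astype(np.float32)
        with pytest.raises(Exception, match="class"):
            clf.fit(X, np.zeros((4, 30)))

    def test_train_config_wrapper_and_loss_decrease(self, rng):
        X = 0.1 * rng.normal(size=(60, 30, 1)).astype(np.float32)
        y = np.zeros((60, 30), dtype=np.int8)
        y[:, 10:20] = 1
        X[:, 10:20] += 1.0
        clf = ApneaTransformerClassifier(num_blocks=1, num_heads=1,
                                         head_size=8, mlp_units=16)
        cfg = TrainConfig(epochs=4, batch_size=16, seed=0)
        train(clf, X, y, cfg)
        assert clf.epochs == 4 and clf.batch_size == 16
        assert clf.history_["loss"][-1] < clf.history_["loss"][0]
        assert clf.history_["lr"] == [1e-3] * 4

    def test_recorded_lr_trace_follows_schedule(self, rng):
        X = rng.normal(size=(8, 10, 1)).astype(np.float32)
        y = (rng.random((8, 30)) < 0.5).astype(np.int8)
        clf = ApneaTransformerClassifier(num_blocks=1, num_heads=1,
                                         head_size=4, ff_hidden=4,
                                         mlp_units=4, epochs=14,
                                         random_state=0)
        clf.fit(X, y)
        lr = clf.history_["lr"]
        assert lr[:10] == [1e-3] * 10
        assert all(a > b for a, b in zip(lr[10:], lr[11:]))
        assert all(v >= 1e-4 for v in lr)


class TestConfusionAndMetrics:
    def test_example_counts(self):
        pred = [1, 1, 0, 0, 1, 0, 1, 1, 0, 0]
        true = [1, 0, 0, 0, 1, 1, 1, 0, 0, 1]
        c = confusion(np.array(pred), np.array(true))
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 2, 2, 3)
        assert c.n == 10

    def test_perfect_prediction(self, rng):
        t = (rng.random(100) < 0.3).astype(int)
        c = confusion(t, t)
        assert c.fp == 0 and c.fn == 0 and c.n == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros(5), np.zeros(6))

    def test_metric_arithmetic_example(self):
        r = compute_metrics(ConfusionCounts(tp=3, fp=1, fn=2, tn=4))
        assert r.accuracy == pytest.approx(0.7)
        assert r.sensitivity == pytest.approx(0.6)
        assert r.specificity == pytest.approx(0.8)
        assert r.precision == pytest.approx(0.75)
        assert r.f1 == pytest.approx(2 / 3, abs=1e-4)

    def test_zero_denominator_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            r = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=7))
        assert math.isnan(r.precision)

    def test_f1_harmonic_identity(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 30, size=4)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = compute_metrics(ConfusionCounts(int(tp), int(fp),
                                                    int(fn), int(tn)))
            assert r.f1 == pytest.approx(
                2 * r.precision * r.sensitivity / (r.precision + r.sensitivity))

    def test_agrees_with_sklearn_on_reconstructed_vectors(self, rng):
        for _ in range(25):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 15, size=4))
            pred = np.array([1] * tp + [1] * fp + [0] * fn + [0] * tn)
            true = np.array([1] * tp + [0] * fp + [1] * fn + [0] * tn)
            r = compute_metrics(confusion(pred, true))
            assert r.accuracy == pytest.approx(accuracy_score(true, pred))
            assert r.sensitivity == pytest.approx(recall_score(true, pred))
            assert r.precision == pytest.approx(precision_score(true, pred))
            assert r.f1 == pytest.approx(f1_score(true, pred))

    def test_auc_extremes(self, rng):
        truths = np.array([0, 0, 1, 1])
        r = compute_metrics(ConfusionCounts(2, 0, 0, 2),
                            probabilities=np.array([0.1, 0.2, 0.8, 0.9]),
                            truths=truths)
        assert r.auc == 1.0

    def test_auc_random_probabilities_near_half(self, rng):
        truths = (rng.random(20000) < 0.3).astype(int)
        probs = rng.random(20000)
        r = compute_metrics(confusion((probs > 0.5).astype(int), truths),
                            probabilities=probs, truths=truths)
        assert r.auc == pytest.approx(0.5, abs=0.02)
        assert r.auc == pytest.approx(
            roc_auc_score(truths, probs), abs=1e-12)


class TestEvents:
    def test_run_length_aggregation(self):
        events = aggregate_events(np.array([0, 1, 1, 1, 0, 0, 1, 0]))
        assert events == [(1.0, 4.0), (6.0, 7.0)]
        assert aggregate_events(np.zeros(10)) == []

    def test_min_duration_filter(self):
        mask = np.array([1, 1, 0, 1, 1, 1, 1])
        assert aggregate_events(mask, min_duration=3) == [(3.0, 7.0)]

    def test_project_aggregate_roundtrip(self, rng):
        for _ in range(50):
            mask = (rng.random(60) < 0.3).astype(np.int8)
            events = aggregate_events(mask)
            np.testing.assert_array_equal(
                project_event_labels(events, 60.0), mask)

    def test_any_overlap_matching(self):
        assert match_events([(5, 20)], [(10, 25)])["matched"] == 1
        r = match_events([(0, 10)], [(20, 30)])
        assert r == {"matched": 0, "missed": 1, "spurious": 1}
        r = match_events([(0, 10), (20, 30)], [(0, 10), (20, 30)])
        assert r == {"matched": 2, "missed": 0, "spurious": 0}

    def test_annotated_event_matched_at_most_once(self):
        r = match_events([(0, 5), (6, 11)], [(0, 12)])
        assert r["matched"] == 1 and r["spurious"] == 1

    def test_overlap_fraction_threshold(self):
        # 5 s overlap of a 15 s annotated event = 1/3
        assert match_events([(5, 20)], [(15, 30)],
                            min_overlap=0.5)["matched"] == 0
        assert match_events([(5, 25)], [(15, 30)],
                            min_overlap=0.5)["matched"] == 1
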