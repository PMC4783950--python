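"""Forest training, confusion metrics, ROC/AUC and the CV harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from golgicsp import (
    ConfusionCounts,
    ForestSpec,
    LabeledFeatureTable,
    confusion_metrics,
    cross_validate,
    roc_auc,
    train_forest,
)

from conftest import random_table

FAST = ForestSpec(n_trees=30, seed=0)


class TestTrainForest:
    def test_linearly_separable_training_accuracy_one(self, rng):
        y = (rng.random(40) < 0.5).astype(int)
        X = np.column_stack([y + 0.1 * rng.normal(size=40), rng.normal(size=40)])
        t = LabeledFeatureTable(X=X, y=y, feature_names=("sep", "noise"))
        model = train_forest(t, FAST)
        assert (model.predict(t.X) == t.y).mean() == 1.0

    def test_score_is_vote_fraction(self, rng):
        t = random_table(rng, 50, 3, informative=1)
        model = train_forest(t, FAST)
        s = model.score_positive(t.X[:10])
        assert np.all((0 <= s) & (s <= 1))
        # vote fractions are multiples of 1/n_trees
        np.testing.assert_allclose(np.rint(s * 30), s * 30, atol=1e-9)

    def test_same_seed_reproducible(self, rng):
        t = random_table(rng, 40, 4, informative=1)
        t2 = LabeledFeatureTable(
            X=np.hstack([t.X, t.X[:, :1]]),
            y=t.y,
            feature_names=t.feature_names + ("dup",),
        )
        a = train_forest(t2, FAST).score_positive(t2.X)
        b = train_forest(t2, FAST).score_positive(t2.X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self, rng):
        t = LabeledFeatureTable(
            X=rng.normal(size=(10, 2)), y=np.ones(10, int), feature_names=("a", "b")
        )
        with pytest.raises(ValueError):
            train_forest(t, FAST)

    def test_pure_noise_cv_is_chance_level(self):
        accs = []
        for seed in range(10):
            t = random_table(np.random.default_rng(seed), 60, 5)
            rep = cross_validate(
                t, folds=10, seed=seed, forest=ForestSpec(n_trees=30, seed=seed)
            )
            accs.append(rep.acc)
        assert 0.35 <= np.mean(accs) <= 0.65


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert m.sn == m.sp == m.acc == m.mcc == 1.0

    def test_hand_computed_example(self):
        m = confusion_metrics(ConfusionCounts(tp=8, fp=1, tn=9, fn=2))
        assert m.sn == pytest.approx(0.8)
        assert m.sp == pytest.approx(0.9)
        assert m.acc == pytest.approx(0.85)
        assert m.mcc == pytest.approx((72 - 2) / np.sqrt(10 * 9 * 10 * 11), abs=1e-4)
        assert m.mcc == pytest.approx(0.7035, abs=1e-4)

    def test_all_predicted_positive_flags_mcc(self):
        m = confusion_metrics(ConfusionCounts(tp=10, fp=10, tn=0, fn=0))
        assert m.sn == 1.0 and m.sp == 0.0 and m.mcc == 0.0
        assert "mcc" in m.zero_denominator

    @given(
        tp=st.integers(0, 50),
        fp=st.integers(0, 50),
        tn=st.integers(0, 50),
        fn=st.integers(0, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_accuracy_is_prevalence_weighted_sn_sp(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
        P, N = tp + fn, tn + fp
        if P and N:
            assert m.acc == pytest.approx((m.sn * P + m.sp * N) / (P + N))
        assert -1 <= m.mcc <= 1
        assert 0 <= m.acc <= 1

    @given(
        tp=st.integers(0, 50),
        fp=st.integers(0, 50),
        tn=st.integers(0, 50),
        fn=st.integers(0, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_mcc_symmetric_under_label_swap(self, tp, fp, tn, fn):
        a = confusion_metrics(ConfusionCounts(tp, fp, tn, fn)).mcc
        b = confusion_metrics(ConfusionCounts(tn, fn, tp, fp)).mcc
        assert a == pytest.approx(b, abs=1e-12)


def auc_concordance_oracle(scores, labels):
    """O(n^2) Mann-Whitney concordance count (ties half)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(1000) < 0.5).astype(int)
        scores = rng.random(1000)
        _, auc = roc_auc(scores, labels)
        assert 0.45 <= auc <= 0.55

    def test_matches_concordance_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(6, 30))
            labels = np.concatenate([[0, 1], (rng.random(n - 2) < 0.5).astype(int)])
            # quantized scores induce ties
            scores = np.round(rng.random(n), 1)
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_concordance_oracle(scores, labels), abs=1e-12)

    def test_curve_monotone_and_anchored(self, rng):
        scores = rng.random(50)
        labels = (rng.random(50) < 0.4).astype(int)
        roc, _ = roc_auc(scores, labels)
        assert np.all(np.diff(roc[:, 0]) >= 0) and np.all(np.diff(roc[:, 1]) >= 0)
        np.testing.assert_array_equal(roc[0], [0, 0])
        np.testing.assert_array_equal(roc[-1], [1, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestCrossValidate:
    def test_jackknife_predicts_each_sample_once(self, rng):
        t = random_table(rng, 24, 3, informative=1)
        rep = cross_validate(t, folds=t.n, seed=0, forest=FAST)
        assert rep.folds == t.n
        total = sum(rep.counts)
        assert total == t.n

    def test_pooled_counts_sum_to_n(self, rng):
        t = random_table(rng, 45, 4, informative=1)
        rep = cross_validate(t, folds=5, seed=0, forest=FAST)
        assert sum(rep.counts) == t.n

    def test_strongly_separated_data_high_accuracy(self, rng):
        y = (rng.random(200) < 0.5).astype(int)
        X = rng.normal(size=(200, 5))
        X[:, :3] += 4.0 * y[:, None]
        t = LabeledFeatureTable(
            X=X, y=y, feature_names=tuple(f"f{i}" for i in range(5))
        )
        rep = cross_validate(t, folds=10, seed=0, forest=FAST)
        assert rep.acc >= 0.95

    def test_smote_inside_folds_handles_imbalance(self, rng):
        y = np.array([1] * 12 + [0] * 48)
        X = rng.normal(size=(60, 3)) + 1.5 * y[:, None]
        t = LabeledFeatureTable(X=X, y=y, feature_names=("a", "b", "c"))
        rep = cross_validate(t, folds=5, seed=0, forest=FAST, smote=True)
        assert sum(rep.counts) == 60
        assert rep.sn > 0.5  # minority no longer swamped

    def test_report_json_round_trip_determinism(self, rng):
        t = random_table(rng, 40, 3, informative=1)
        a = cross_validate(t, folds=5, seed=3, forest=FAST).to_dict()
        b = cross_validate(t, folds=5, seed=3, forest=FAST).to_dict()
        assert a == b

    def test_bad_fold_count_rejected(self, rng):
        t = random_table(rng, 10, 2)
        with pytest.raises(ValueError):
            cross_validate(t, folds=1, seed=0, forest=FAST)
        with pytest.raises(ValueError):
            cross_validate(t, folds=11, seed=0, forest=FAST)
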