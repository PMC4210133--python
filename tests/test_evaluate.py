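import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import (
    cohen_kappa_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)

from nanoct.classify import ClassifierSpec
from nanoct.evaluate import (
    ConfusionMatrix,
    confusion_metrics,
    learning_curve,
    per_class_metrics,
    roc_auc,
    run_validation,
    split_weight_matrices,
    stratified_kfold,
)
from nanoct.preprocess import NGramBag

NANO, CTRL = "nano", "non-nano"


def cm_to_labels(cm):
    y_true = [NANO] * (cm.tp + cm.fn) + [CTRL] * (cm.fp + cm.tn)
    y_pred = ([NANO] * cm.tp + [CTRL] * cm.fn + [NANO] * cm.fp + [CTRL] * cm.tn)
    return np.array(y_true), np.array(y_pred)


class TestStratifiedKFold:
    def test_balanced_thousand_docs_ten_folds(self):
        labels = [NANO] * 500 + [CTRL] * 500
        folds = stratified_kfold(labels, k=10, seed=4)
        y = np.array(labels)
        assert sorted(np.concatenate(folds).tolist()) == list(range(1000))
        for f in folds:
            assert len(f) == 100
            assert (y[f] == NANO).sum() == 50

    def test_small_balanced_case(self):
        labels = [NANO] * 5 + [CTRL] * 5
        folds = stratified_kfold(labels, k=5, seed=0)
        y = np.array(labels)
        for f in folds:
            assert len(f) == 2
            assert (y[f] == NANO).sum() == 1

    def test_seeded_reproducibility(self):
        labels = [NANO] * 30 + [CTRL] * 30
        a = stratified_kfold(labels, k=3, seed=9)
        b = stratified_kfold(labels, k=3, seed=9)
        c = stratified_kfold(labels, k=3, seed=10)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))
        assert [len(f) for f in a] == [len(f) for f in c]

    def test_k_larger_than_min_class_rejected(self):
        with pytest.raises(ValueError, match="smallest class"):
            stratified_kfold([NANO] * 3 + [CTRL] * 50, k=5)


class TestConfusionMetrics:
    def test_printed_loo_worked_example(self):
        # confusion matrix implied by a weighted TP rate of 0.955 on the
        # balanced 1000-document corpus
        cm = ConfusionMatrix(tp=478, fn=22, tn=477, fp=23)
        m = confusion_metrics(cm)
        assert m.tpr == pytest.approx(0.955)
        assert m.kappa == pytest.approx(0.910)
        assert 0.905 <= m.mcc <= 0.915

    def test_perfect_matrix(self):
        m = confusion_metrics(ConfusionMatrix(tp=10, fn=0, tn=10, fp=0))
        for key in ("precision", "recall", "f_measure", "mcc", "kappa"):
            assert getattr(m, key) == 1.0

    def test_all_predicted_positive_on_balanced_corpus(self):
        m = confusion_metrics(ConfusionMatrix(tp=50, fn=0, tn=0, fp=50))
        assert m.kappa == 0.0
        assert m.mcc == 0.0

    def test_weighted_values_match_sklearn_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            tp, fp, tn, fn = rng.integers(0, 40, size=4)
            cm = ConfusionMatrix(int(tp), int(fp), int(tn), int(fn))
            if cm.total == 0:
                continue
            y_true, y_pred = cm_to_labels(cm)
            m = confusion_metrics(cm)
            kwargs = dict(average="weighted", zero_division=0)
            assert m.precision == pytest.approx(
                precision_score(y_true, y_pred, **kwargs), abs=1e-12)
            assert m.recall == pytest.approx(
                recall_score(y_true, y_pred, **kwargs), abs=1e-12)
            assert m.f_measure == pytest.approx(
                f1_score(y_true, y_pred, **kwargs), abs=1e-12)
            if len(set(y_true)) == 2 or len(set(y_pred)) == 2:
                assert m.kappa == pytest.approx(
                    cohen_kappa_score(y_true, y_pred), abs=1e-12)
                assert m.mcc == pytest.approx(
                    matthews_corrcoef(y_true, y_pred), abs=1e-12)

    @settings(derandomize=True, max_examples=300)
    @given(st.integers(0, 200), st.integers(0, 200), st.integers(1, 200))
    def test_balanced_corpus_kappa_identity(self, tp, fp, n):
        """With balanced true classes, expected chance agreement is 1/2
        whatever the prediction marginals, so kappa = 2*accuracy - 1."""
        tp, fp = min(tp, n), min(fp, n)
        cm = ConfusionMatrix(tp=tp, fn=n - tp, fp=fp, tn=n - fp)
        m = confusion_metrics(cm)
        assert m.kappa == pytest.approx(2 * m.accuracy - 1, abs=1e-12)

    def test_per_class_view_supports(self):
        per = per_class_metrics(ConfusionMatrix(tp=8, fn=2, tn=5, fp=5))
        assert per["positive"]["support"] == 10
        assert per["negative"]["support"] == 10
        assert per["positive"]["recall"] == pytest.approx(0.8)
        assert per["negative"]["recall"] == pytest.approx(0.5)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionMatrix(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [NANO, NANO, CTRL, CTRL])
        assert auc == 1.0

    def test_all_scores_equal_gives_half(self):
        auc, _ = roc_auc([0.5] * 6, [NANO] * 3 + [CTRL] * 3)
        assert auc == 0.5

    def test_worked_example(self):
        auc, _ = roc_auc([0.9, 0.4, 0.6, 0.1], [NANO, NANO, CTRL, CTRL])
        assert auc == 0.75

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(4, 200))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.choice([NANO, CTRL], size=n)
            if len(set(labels)) < 2:
                continue
            pos = scores[labels == NANO]
            neg = scores[labels == CTRL]
            pairs = sum(
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            )
            want = pairs / (len(pos) * len(neg))
            got, _ = roc_auc(scores, labels)
            assert got == pytest.approx(want, abs=1e-12)
            assert got == pytest.approx(
                roc_auc_score((labels == NANO).astype(int), scores), abs=1e-12)

    def test_roc_points_are_monotone_and_bracketed(self):
        rng = np.random.default_rng(8)
        scores = rng.random(50)
        labels = rng.choice([NANO, CTRL], size=50)
        _, pts = roc_auc(scores, labels)
        assert pts[0][:2] == (0.0, 0.0)
        assert pts[-1][:2] == (1.0, 1.0)
        fprs = [p[0] for p in pts]
        tprs = [p[1] for p in pts]
        assert fprs == sorted(fprs)
        assert tprs == sorted(tprs)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.4], [NANO, NANO])


def toy_bags(n_per_class=6):
    """Separable bag corpus: nano docs carry 'zzz', controls carry 'xxx'."""
    bags, labels = [], []
    for i in range(n_per_class):
        bags.append(NGramBag(1, {"zzz": 2 + i % 2, "bg": 1}))
        labels.append(NANO)
        bags.append(NGramBag(1, {"xxx": 2 + i % 2, "bg": 1}))
        labels.append(CTRL)
    return bags, labels


class TestRunValidation:
    SPEC = ClassifierSpec(family="l1_logreg", seed=0)

    def test_self_consistency_on_separable_toy(self):
        bags, labels = toy_bags()
        rep = run_validation(bags, labels, "frequency", self.SPEC,
                             mode="self_consistency")
        assert rep.pooled.accuracy == 1.0

    def test_loo_pools_exactly_n_predictions(self):
        bags, labels = toy_bags(4)
        rep = run_validation(bags, labels, "binary", self.SPEC, mode="loo")
        assert rep.confusion.total == len(bags)
        assert rep.per_fold is None and rep.sem is None

    def test_kfold_report_shape_and_sem_definition(self):
        bags, labels = toy_bags(10)
        rep = run_validation(bags, labels, "idf", self.SPEC, mode="kfold",
                             seed=3, k=5)
        assert len(rep.per_fold) == 5
        accs = [m.accuracy for m in rep.per_fold]
        assert rep.sem["accuracy"] == pytest.approx(
            np.std(accs, ddof=1) / math.sqrt(5))
        total = sum(len(f) for f in rep.fold_assignment)
        assert total == len(bags) == rep.confusion.total

    def test_kfold_pooled_accuracy_near_fold_mean(self, signal_synth,
                                                  l1_idf_spec):
        sc, bags = signal_synth
        rep = run_validation(bags, sc.corpus.labels, "idf", l1_idf_spec,
                             mode="kfold", seed=0)
        fold_accs = [m.accuracy for m in rep.per_fold]
        sem = rep.sem["accuracy"]
        spread = max(3 * sem, 1e-9)
        assert abs(rep.pooled.accuracy - np.mean(fold_accs)) <= spread

    def test_unknown_mode_rejected(self):
        bags, labels = toy_bags(3)
        with pytest.raises(ValueError, match="unknown mode"):
            run_validation(bags, labels, "binary", self.SPEC, mode="bootstrap")


class TestNoLeakage:
    def test_test_only_feature_absent_from_training_vocabulary(self):
        bags, labels = toy_bags(4)
        bags[0] = NGramBag(1, {**bags[0].counts, "leakprobe": 5})
        train_idx = np.arange(1, len(bags))
        Xtr, Xte, vocab = split_weight_matrices(
            bags, train_idx, np.array([0]), "tfidf")
        assert "leakprobe" not in vocab.features
        assert "leakprobe" not in vocab.df
        assert Xtr.shape[1] == Xte.shape[1] == len(vocab)


class TestLearningCurve:
    SPEC = ClassifierSpec(family="l1_logreg", seed=0)

    def test_default_fraction_grid_endpoints(self):
        bags, labels = toy_bags(20)
        res = learning_curve(bags, labels, "binary", self.SPEC, seed=0)
        fr = [r["fraction"] for r in res]
        assert fr[0] == 0.10 and fr[-1] == 0.95

    def test_half_split_balanced_within_one(self):
        bags, labels = toy_bags(15)
        res = learning_curve(bags, labels, "binary", self.SPEC,
                             fractions=[0.5], seed=0)
        assert abs(res[0]["n_train"] - res[0]["n_test"]) <= 2

    def test_extreme_fraction_rejected(self):
        bags, labels = toy_bags(3)
        with pytest.raises(ValueError, match="fraction"):
            learning_curve(bags, labels, "binary", self.SPEC,
                           fractions=[0.01], seed=0)

    def test_nonincreasing_fractions_rejected(self):
        bags, labels = toy_bags(5)
        with pytest.raises(ValueError):
            learning_curve(bags, labels, "binary", self.SPEC,
                           fractions=[0.5, 0.3], seed=0)
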