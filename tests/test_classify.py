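import numpy as np
import pytest

from brcapath.classify import (
    ClassifierSpec,
    build_report,
    confusion_matrix,
    five_fold_cv_predict,
    fourclass_model,
    pairwise_models,
    report_metrics,
    roc_auc,
)
from brcapath.exceptions import InputError


class TestFiveFoldCV:
    def test_separable_classes_reach_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(10, 1, (50, 3))])
        y = ["neg"] * 50 + ["pos"] * 50
        preds = five_fold_cv_predict(x, y, ClassifierSpec(seed=1))
        assert len(preds) == 100
        acc = np.mean([preds[f"s{i}"][0] == y[i] for i in range(100)])
        assert acc == 1.0

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(1)
        aucs = []
        for seed in range(20):
            x = rng.normal(size=(60, 4))
            y = ["a"] * 30 + ["b"] * 30
            preds = five_fold_cv_predict(x, y, ClassifierSpec(seed=seed))
            scores = [preds[f"s{i}"][1] for i in range(60)]
            _, auc = roc_auc(scores, [lbl == "b" for lbl in y])
            aucs.append(auc)
        assert 0.4 <= float(np.mean(aucs)) <= 0.6

    def test_same_seed_reproduces_predictions(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 3))
        y = ["a"] * 20 + ["b"] * 20
        p1 = five_fold_cv_predict(x, y, ClassifierSpec(seed=7))
        p2 = five_fold_cv_predict(x, y, ClassifierSpec(seed=7))
        assert p1 == p2

    def test_small_class_rejected_with_guidance(self):
        x = np.zeros((8, 2))
        y = ["a"] * 4 + ["b"] * 4
        with pytest.raises(InputError, match="drop"):
            five_fold_cv_predict(x, y, ClassifierSpec())

    def test_every_sample_predicted_exactly_once(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(37, 2))
        y = ["a"] * 20 + ["b"] * 17
        preds = five_fold_cv_predict(x, y, ClassifierSpec(seed=0))
        assert sorted(preds) == sorted(f"s{i}" for i in range(37))


class TestConfusionAndMetrics:
    def test_perfect_predictions_identity(self):
        counts, norm, classes = confusion_matrix(["a", "b", "a"], ["a", "b", "a"])
        assert np.array_equal(norm, np.eye(2))

    def test_hand_count(self):
        counts, _, _ = confusion_matrix(["a", "a", "b", "b"], ["a", "b", "b", "b"])
        assert np.array_equal(counts, [[1, 1], [0, 2]])

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(4)
        classes = ["x", "y", "z"]
        actual = [classes[i] for i in rng.integers(0, 3, 200)]
        predicted = [classes[i] for i in rng.integers(0, 3, 200)]
        counts, _, _ = confusion_matrix(actual, predicted, classes)
        for i, a in enumerate(classes):
            for j, p in enumerate(classes):
                assert counts[i, j] == sum(
                    1 for x, y in zip(actual, predicted) if x == a and y == p
                )

    def test_unknown_label_rejected(self):
        with pytest.raises(InputError):
            confusion_matrix(["a"], ["q"], classes=["a", "b"])

    def test_formula_evaluation(self):
        # TP=9, FN=1, FP=3
        counts = np.array([[9, 1], [3, 7]])
        per_class, averages, flags = report_metrics(counts, ["pos", "neg"])
        assert per_class["pos"]["precision"] == pytest.approx(0.75)
        assert per_class["pos"]["recall"] == pytest.approx(0.9)
        assert per_class["pos"]["f1"] == pytest.approx(2 * 0.75 * 0.9 / 1.65)
        assert per_class["pos"]["f1"] == pytest.approx(0.8182, abs=1e-4)

    def test_never_predicted_class_flagged_zero(self):
        counts = np.array([[3, 0], [2, 0]])
        per_class, _, flags = report_metrics(counts, ["a", "b"])
        assert per_class["b"]["precision"] == 0.0 and per_class["b"]["recall"] == 0.0
        assert "precision[b]" in flags

    def test_weighted_recall_equals_accuracy(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            actual = [str(i) for i in rng.integers(0, 3, 100)]
            predicted = [str(i) for i in rng.integers(0, 3, 100)]
            counts, _, classes = confusion_matrix(actual, predicted, ["0", "1", "2"])
            _, averages, _ = report_metrics(counts, classes)
            accuracy = np.mean([a == p for a, p in zip(actual, predicted)])
            assert averages["recall"] == pytest.approx(accuracy, abs=1e-12)


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        roc, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        roc, auc = roc_auc([1.0] * 10, [True] * 4 + [False] * 6)
        assert auc == pytest.approx(0.5)
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            scores = rng.integers(0, 15, 100).astype(float)  # heavy ties
            labels = rng.random(100) < 0.4
            if labels.all() or not labels.any():
                continue
            _, auc = roc_auc(scores, labels)
            pos, neg = scores[labels], scores[~labels]
            u = (
                np.sum(pos[:, None] > neg[None, :])
                + 0.5 * np.sum(pos[:, None] == neg[None, :])
            ) / (len(pos) * len(neg))
            assert abs(auc - u) < 1e-12

    def test_negation_identity(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(-scores, labels)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc([1.0, 2.0], [True, True])


class TestEndToEndModels:
    def test_fourclass_report_is_consistent(self, default_cohort):
        from brcapath.pathway_score import score_matrix

        expr, truth, coll = default_cohort
        core_pws = [n for n, t in truth.pathway_truth.items() if t.enriched_for_core]
        scores = score_matrix(expr, coll, pathways=core_pws)
        report = fourclass_model(scores, expr.labels, ClassifierSpec(seed=5))
        assert report.confusion.sum() == len(expr.samples)
        supports = report.confusion.sum(axis=1)
        for c, s in zip(report.classes, supports):
            assert report.per_class[c]["support"] == s
        # weighted recall is overall accuracy
        acc = np.trace(report.confusion) / report.confusion.sum()
        assert report.averages["recall"] == pytest.approx(acc, abs=1e-12)
        assert acc > 0.5  # planted gradient is learnable

    def test_pairwise_models_on_default_cohort(self, default_cohort, default_screen):
        expr, truth, coll = default_cohort
        _, screen_result = default_screen
        reports = pairwise_models(expr, screen_result, coll, ClassifierSpec(seed=5))
        assert set(reports) == {("LA", "LB"), ("LA", "TN"), ("LB", "TN")}
        for pair, rep in reports.items():
            assert rep.auc is not None
            assert rep.roc[0] == (0.0, 0.0) and rep.roc[-1] == (1.0, 1.0)
            fprs = [p[0] for p in rep.roc]
            assert fprs == sorted(fprs)
        assert reports[("LA", "TN")].auc >= 0.9
        assert reports[("LB", "TN")].auc >= 0.9

    def test_pairwise_requires_enriched_pathways(self, default_cohort, default_screen):
        from brcapath.io import GeneSetCollection

        expr, truth, coll = default_cohort
        _, screen_result = default_screen
        null_sets = {
            n: m for n, m in coll.sets.items() if n.startswith("NULL")
        }
        null_coll = GeneSetCollection(null_sets, coll.universe)
        with pytest.raises(InputError, match="no pathway enriched"):
            pairwise_models(expr, screen_result, null_coll, ClassifierSpec(seed=5))

    def test_single_feature_pathway_pipeline_completes(self):
        # degenerate width: a one-column feature matrix still trains
        rng = np.random.default_rng(8)
        x = np.vstack([rng.normal(0, 1, (30, 1)), rng.normal(4, 1, (30, 1))])
        y = ["a"] * 30 + ["b"] * 30
        preds = five_fold_cv_predict(x, y, ClassifierSpec(seed=0))
        report = build_report(
            preds, {f"s{i}": y[i] for i in range(60)}, ["a", "b"]
        )
        assert report.auc > 0.9
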