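import numpy as np
import pytest

import canes
from canes.panel_eval import loocv_panel

from conftest import auc_concordance_oracle, random_confusion


class TestConfusionMeasures:
    def test_worked_arithmetic_example(self):
        c = canes.ConfusionCounts(tp=40, tn=30, fp=10, fn=20)
        m = canes.confusion_measures(c)
        assert m["sn"] == pytest.approx(0.6667, abs=5e-5)
        assert m["sp"] == pytest.approx(0.75)
        assert m["ba"] == pytest.approx(0.7083, abs=5e-5)
        assert m["ac"] == pytest.approx(0.70)
        assert m["ppv"] == pytest.approx(0.80)
        assert m["npv"] == pytest.approx(0.60)
        assert m["fdr"] == pytest.approx(0.20)
        assert m["fpr"] == pytest.approx(0.25)
        assert m["f1"] == pytest.approx(0.7273, abs=5e-5)

    def test_perfect_classifier(self):
        m = canes.confusion_measures(canes.ConfusionCounts(50, 50, 0, 0))
        for k in ("ac", "sn", "sp", "ba", "ppv", "npv", "f1"):
            assert m[k] == 1.0
        assert m["fpr"] == 0.0 and m["fdr"] == 0.0

    def test_degenerate_denominators_are_nan_not_errors(self):
        m = canes.confusion_measures(canes.ConfusionCounts(tp=0, fp=0, tn=10, fn=10))
        assert np.isnan(m["ppv"]) and np.isnan(m["fdr"])
        assert m["sp"] == 1.0 and m["sn"] == 0.0 and m["ba"] == 0.5

    def test_identities_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            c = random_confusion(rng)
            m = canes.confusion_measures(c)
            if not np.isnan(m["ba"]):
                assert m["ba"] == pytest.approx((m["sn"] + m["sp"]) / 2, abs=1e-12)
            if not np.isnan(m["ppv"]):
                assert m["fdr"] == pytest.approx(1 - m["ppv"], abs=1e-12)
            if not np.isnan(m["sp"]):
                assert m["fpr"] == pytest.approx(1 - m["sp"], abs=1e-12)


class TestAuc:
    def test_separated_ties_and_worked_example(self):
        assert canes.auc_from_scores([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0
        assert canes.auc_from_scores([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5
        # 3 of 4 pairs concordant
        assert canes.auc_from_scores([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_matches_concordance_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            labels = np.zeros(n, int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], size=n)
            assert canes.auc_from_scores(scores, labels) == pytest.approx(
                auc_concordance_oracle(scores, labels), abs=1e-12
            )

    def test_one_class_is_error(self):
        with pytest.raises(canes.CanesError):
            canes.auc_from_scores([1, 2, 3], [1, 1, 1])


class TestLoocv:
    def test_separable_marker_all_measures_one(self):
        ds = canes.generate_dataset(20, 20, 50, informative=[(0, 4.0)], seed=5)
        result = canes.evaluate_loocv(ds, ["p_0000"], canes.default_classifiers(seed=2))
        for name, panel in result.per_classifier.items():
            for m in canes.MEASURES:
                expected = 0.0 if m in ("fpr", "fdr") else 1.0
                assert panel[m] == pytest.approx(expected), (name, m)

    def test_label_independent_data_never_looks_informative(self, svm_only):
        # pooled LOOCV scores are pessimistic under the null at small n (each
        # fold's model is nudged away from its held-out sample), so the null
        # AUC sits at or below chance — crucially it must never sit above it,
        # and the size-matched empirical null shares (and thus absorbs) the
        # same downward bias
        rng = np.random.default_rng(11)
        aucs = []
        for rep in range(20):
            ds = canes.generate_dataset(15, 15, 30, seed=100 + rep)
            result = canes.evaluate_loocv(ds, ["p_0000", "p_0001"], svm_only)
            aucs.append(result.average.auc)
        assert 0.2 < np.mean(aucs) < 0.57

    def test_single_sample_class_is_error(self, svm_only):
        values = np.random.default_rng(0).normal(size=(5, 6))
        ds = canes.ExpressionDataset(
            values=values, probe_ids=[f"p{i}" for i in range(5)],
            sample_ids=[f"s{j}" for j in range(6)],
            labels=np.array(["cancer"] + ["normal"] * 5, dtype=object),
        )
        with pytest.raises(canes.CanesError):
            canes.evaluate_loocv(ds, ["p0"], svm_only)

    def test_invariant_to_sample_and_feature_permutation(self, cldn_ds, svm_only):
        base = canes.evaluate_loocv(cldn_ds, ["CLDN1", "CLDN18"], svm_only)
        perm = np.random.default_rng(7).permutation(cldn_ds.n_samples)
        shuffled = canes.ExpressionDataset(
            values=cldn_ds.values[:, perm],
            probe_ids=cldn_ds.probe_ids,
            sample_ids=[cldn_ds.sample_ids[i] for i in perm],
            labels=cldn_ds.labels[perm],
            gene_map=cldn_ds.gene_map,
        )
        res_shuffled = canes.evaluate_loocv(shuffled, ["CLDN1", "CLDN18"], svm_only)
        res_reordered = canes.evaluate_loocv(cldn_ds, ["CLDN18", "CLDN1"], svm_only)
        for m in canes.MEASURES:
            assert res_shuffled.average[m] == pytest.approx(base.average[m], abs=1e-9)
            assert res_reordered.average[m] == pytest.approx(base.average[m], abs=1e-9)

    def test_average_is_mean_of_defined_classifier_measures(self, cldn_ds):
        result = canes.evaluate_loocv(
            cldn_ds, ["CLDN18"], canes.default_classifiers(seed=3, names=("svm", "cart"))
        )
        for m in canes.MEASURES:
            vals = [p[m] for p in result.per_classifier.values() if not np.isnan(p[m])]
            assert result.average[m] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_auc_nondecreasing_in_planted_effect(self, svm_only):
        means = []
        for effect in (0.0, 1.0, 2.0):
            aucs = []
            for rep in range(5):
                ds = canes.generate_dataset(
                    15, 15, 30, informative=[(0, effect)], seed=500 + rep
                )
                res = canes.evaluate_loocv(ds, ["p_0000"], svm_only)
                aucs.append(res.average.auc)
            means.append(np.mean(aucs))
        assert means[0] <= means[1] <= means[2]


class TestTrainTest:
    def test_train_equals_test_separable(self, svm_only):
        ds = canes.generate_dataset(20, 20, 50, informative=[(0, 4.0)], seed=6)
        result, _ = canes.evaluate_train_test(ds, ds, ["p_0000"], svm_only)
        assert result.average.auc == 1.0 and result.average.ba == 1.0

    def test_stored_model_invariant_to_test_sample_order(self, tmp_path, svm_only):
        train = canes.generate_dataset(15, 15, 40, informative=[(0, 2.0)], seed=8)
        test = canes.generate_dataset(12, 14, 40, informative=[(0, 2.0)], seed=9)
        _, model = canes.evaluate_train_test(train, test, ["p_0000"], svm_only)
        path = model.save(tmp_path / "panel.model")
        loaded = canes.StoredModel.load(path)
        perm = np.random.default_rng(2).permutation(test.n_samples)
        shuffled = canes.ExpressionDataset(
            values=test.values[:, perm], probe_ids=test.probe_ids,
            sample_ids=[test.sample_ids[i] for i in perm],
            labels=test.labels[perm], gene_map=test.gene_map,
        )
        a, b = loaded.evaluate(test).average, loaded.evaluate(shuffled).average
        np.testing.assert_allclose(
            [a[m] for m in canes.MEASURES],
            [b[m] for m in canes.MEASURES],
            atol=1e-12, equal_nan=True,
        )

    def test_effect_removed_in_test_gives_chance_auc(self, svm_only):
        aucs = []
        for rep in range(10):
            train = canes.generate_dataset(20, 20, 40, informative=[(0, 3.0)],
                                           seed=30 + rep)
            test = canes.generate_dataset(20, 20, 40, seed=60 + rep)
            result, _ = canes.evaluate_train_test(train, test, ["p_0000"], svm_only)
            aucs.append(result.average.auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_marker_missing_in_test_is_error(self, svm_only):
        train = canes.generate_dataset(10, 10, 20, seed=1)
        test = canes.generate_dataset(10, 10, 5, seed=2)
        model = canes.fit_panel_model(train, ["p_0015"], svm_only)
        with pytest.raises(canes.CanesError):
            model.evaluate(test)


def test_loocv_skips_and_reports_one_class_training_folds(svm_only):
    # with a single positive sample, its fold has one-class training data:
    # the fold is skipped and disclosed, the remaining folds are pooled
    X = np.random.default_rng(0).normal(size=(4, 2))
    y = np.array([1, 0, 0, 0])
    panel, n_skipped = loocv_panel(X, y, svm_only[0])
    assert n_skipped == 1
    assert np.isnan(panel.auc)  # pooled held-out samples are one-class
    assert panel.counts.total == 3
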