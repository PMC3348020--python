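"""Increase/decrease discrimination: encoding, classifiers, jack-knife, scoring."""

import numpy as np
import pandas as pd
import pytest

from mutprop.discrimination import (
    METHODS,
    LabeledDataset,
    confusion_metrics,
    encode_for_classification,
    evaluate_methods,
    jackknife,
    jackknife_strict,
    label_by_sign,
    self_consistency,
    train_and_classify,
)
from mutprop.errors import (
    LabelingError,
    SingleClassError,
    UndefinedStatisticError,
    UnknownMethodError,
)
from mutprop.features import delta_property
from mutprop.synthetic_data import SimulationConfig, simulate_classification_dataset


@pytest.fixture(scope="module")
def separable(table49):
    """A wide-margin 15/13 increase/decrease set with its source dataset."""
    cfg = SimulationConfig(seed=101, class_margin=5.0)
    dataset, truth = simulate_classification_dataset(table49, cfg)
    data = encode_for_classification(table49, dataset, list(truth.true_subset), k=1)
    return dataset, truth, data


def two_blob_data(n=28, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    n1 = n // 2
    X = np.vstack(
        [rng.normal(0, 1, size=(n1, 2)), rng.normal(sep, 1, size=(n - n1, 2))]
    )
    labels = np.r_[np.zeros(n1, dtype=int), np.ones(n - n1, dtype=int)]
    return LabeledDataset(features=pd.DataFrame(X, columns=["f0", "f1"]), labels=labels)


class TestLabeling:
    def test_sign_to_label(self):
        np.testing.assert_array_equal(label_by_sign([1.2, -0.3]), [1, 0])

    def test_zero_response_unlabelable(self):
        with pytest.raises(LabelingError, match="0"):
            label_by_sign([1.0, 0.0, -1.0])

    def test_single_class_flagged_untrainable(self):
        data = LabeledDataset(
            features=pd.DataFrame({"f": [1.0, 2.0, 3.0]}), labels=np.ones(3, dtype=int)
        )
        assert not data.trainable
        with pytest.raises(SingleClassError):
            train_and_classify(data, "logistic")


class TestEncoding:
    def test_four_features_per_property(self, separable, table49):
        dataset, truth, data = separable
        assert data.features.shape == (28, 4 * len(truth.true_subset))

    def test_delta_column_matches_delta_property(self, separable, table49):
        dataset, truth, data = separable
        pid = truth.true_subset[0]
        expect = [
            delta_property(table49, pid, r.wild, r.mutant) for r in dataset.records
        ]
        np.testing.assert_allclose(data.features[f"delta:{pid}"], expect)

    def test_default_class_counts(self, separable):
        _, _, data = separable
        assert (data.n_increase, data.n_decrease) == (15, 13)


class TestConfusionMetrics:
    def test_reconstructed_integer_solution(self):
        """TP=14, FP=1, TN=12, FN=1 gives 93.3% / 92.3% / 92.9% on 15 vs 13."""
        cm = confusion_metrics(14, 1, 12, 1)
        assert round(cm.sensitivity, 3) == 0.933
        assert round(cm.specificity, 3) == 0.923
        assert round(cm.accuracy, 3) == 0.929

    def test_perfect_and_inverted(self):
        assert confusion_metrics(15, 0, 13, 0).accuracy == 1.0
        worst = confusion_metrics(0, 13, 0, 15)
        assert (worst.sensitivity, worst.specificity, worst.accuracy) == (0, 0, 0)

    def test_accuracy_is_weighted_mean_of_sens_spec(self):
        cm = confusion_metrics(9, 4, 8, 7)
        w_pos = (cm.tp + cm.fn) / cm.n
        w_neg = (cm.tn + cm.fp) / cm.n
        assert cm.accuracy == pytest.approx(
            w_pos * cm.sensitivity + w_neg * cm.specificity
        )

    def test_label_flip_swaps_sensitivity_and_specificity(self):
        cm = confusion_metrics(9, 4, 8, 7)
        flipped = confusion_metrics(cm.tn, cm.fn, cm.tp, cm.fp)
        assert flipped.sensitivity == pytest.approx(cm.specificity)
        assert flipped.specificity == pytest.approx(cm.sensitivity)
        assert flipped.accuracy == pytest.approx(cm.accuracy)

    def test_undefined_denominators(self):
        with pytest.raises(UndefinedStatisticError):
            _ = confusion_metrics(0, 3, 2, 0).sensitivity
        with pytest.raises(UndefinedStatisticError):
            _ = confusion_metrics(3, 0, 0, 2).specificity


class TestClassifiers:
    def test_logistic_separates_wide_margin(self):
        data = two_blob_data()
        cm = self_consistency(data, "logistic")
        assert cm.accuracy == 1.0

    def test_1nn_memorizes_training_data(self, separable):
        _, _, data = separable
        assert self_consistency(data, "knn1").accuracy == 1.0

    def test_deterministic_given_seed(self, separable):
        _, _, data = separable
        a = jackknife(data, "tree", seed=3)
        b = jackknife(data, "tree", seed=3)
        assert a == b

    def test_unknown_method_rejected(self, separable):
        _, _, data = separable
        with pytest.raises(UnknownMethodError):
            train_and_classify(data, "perceptron9")

    def test_count_conservation(self, separable):
        _, _, data = separable
        cm = self_consistency(data, "naive_bayes")
        assert cm.tp + cm.fn == data.n_increase
        assert cm.tn + cm.fp == data.n_decrease
        assert cm.n == data.n


class TestJackknife:
    def test_wide_margin_perfect(self):
        data = two_blob_data(n=28, sep=10.0, seed=1)
        assert jackknife(data, "logistic").accuracy == 1.0

    def test_matches_manual_leave_one_out(self):
        """Oracle: refit on the N-1 remaining rows by hand for every fold."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        data = two_blob_data(n=16, sep=2.0, seed=2)  # overlapping: non-trivial folds
        cm = jackknife(data, "logistic", seed=0)
        X, labels = data.features.to_numpy(), data.labels
        manual = np.empty(len(labels), dtype=int)
        for i in range(len(labels)):
            keep = [j for j in range(len(labels)) if j != i]
            clf = make_pipeline(
                StandardScaler(), LogisticRegression(max_iter=5000, random_state=0)
            )
            clf.fit(X[keep], labels[keep])
            manual[i] = clf.predict(X[i : i + 1])[0]
        expect = confusion_metrics(
            int(((labels == 1) & (manual == 1)).sum()),
            int(((labels == 0) & (manual == 1)).sum()),
            int(((labels == 0) & (manual == 0)).sum()),
            int(((labels == 1) & (manual == 0)).sum()),
        )
        assert cm == expect

    def test_single_member_class_policy(self):
        rng = np.random.default_rng(5)
        data = LabeledDataset(
            features=pd.DataFrame({"f": rng.normal(size=6)}),
            labels=np.array([1, 0, 0, 0, 0, 0]),
        )
        with pytest.warns(UserWarning, match="single member"):
            cm = jackknife(data, "logistic")
        assert cm.n == 6  # every record predicted exactly once

    def test_random_labels_near_chance(self, table49):
        """Null: features carry no signal, so leave-one-out is near coin-flip."""
        accs = []
        for seed in range(8):
            cfg = SimulationConfig(seed=seed, betas=(0.0, 0.0, 0.0),
                                   true_subset=tuple(table49.property_ids[:3]),
                                   class_margin=0.0)
            dataset, truth = simulate_classification_dataset(table49, cfg)
            data = encode_for_classification(table49, dataset, list(truth.true_subset))
            accs.append(jackknife(data, "logistic").accuracy)
        assert 0.2 <= np.mean(accs) <= 0.8


class TestEvaluation:
    def test_all_methods_reported_with_max(self, separable):
        _, _, data = separable
        report = evaluate_methods(data, seed=0)
        assert set(report.metrics) == set(METHODS)
        method, cm = report.best("self")
        assert cm.accuracy == max(m["self"].accuracy for m in report.metrics.values())
        frame = report.to_frame()
        assert set(frame["mode"]) == {"self", "jackknife"}

    def test_report_round_trip(self, separable, tmp_path):
        _, _, data = separable
        report = evaluate_methods(data, ["logistic"], seed=0)
        report.write_tsv(tmp_path / "e.tsv")
        report.write_json(tmp_path / "e.json")
        back = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert back.loc[0, "TP"] + back.loc[0, "FN"] == data.n_increase

    def test_strict_jackknife_runs_and_scores(self, separable, table49):
        dataset, truth, _ = separable
        cm = jackknife_strict(table49, dataset, "logistic", n_properties=3, k=1)
        assert cm.n == dataset.n
        assert 0.0 <= cm.accuracy <= 1.0
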