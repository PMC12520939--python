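import numpy as np
import pytest

from hsrpi.classification import (
    RankError,
    autoscale,
    apply_scaler,
    fit_oplsda,
    load_model,
    predict_oplsda,
    save_model,
    scores_plot_data,
)

from conftest import three_class_fixture
from oracles import pls2da_oracle


def one_hot(labels, classes):
    Y = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        Y[i, classes.index(l)] = 1.0
    return Y


class TestAutoscale:
    def test_two_point_column_uses_sample_sd(self):
        sc = autoscale(np.array([[1.0], [3.0]]))
        assert np.allclose(sc.X[:, 0], [-0.70710678, 0.70710678])

    def test_constant_column_becomes_zero_with_unit_sd(self):
        sc = autoscale(np.column_stack([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))
        assert np.all(sc.X[:, 1] == 0.0)
        assert sc.sds[1] == 1.0

    def test_reapplying_scaler_is_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(2, 3, (20, 4))
        sc = autoscale(X)
        assert np.allclose(apply_scaler(sc, X), sc.X, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            autoscale(np.ones((1, 3)))


class TestFitOplsda:
    def test_no_ortho_limit_equals_pls2da_oracle(self):
        rng = np.random.default_rng(1)
        X, labels, _ = three_class_fixture(rng)
        sc = autoscale(X)
        model = fit_oplsda(sc, labels, A=2, A_ortho=0)
        pred = predict_oplsda(model, X)
        Y = one_hot(labels, model.class_labels)
        Yhat_oracle = pls2da_oracle(sc.X, Y, A=2)
        assert np.abs(pred.predicted_Y - Yhat_oracle).max() < 1e-9

    def test_weight_concentrates_on_informative_feature(self):
        rng = np.random.default_rng(2)
        n = 40
        X = rng.normal(0, 1, (2 * n, 5))
        X[n:, 0] += 5.0  # classes differ only along feature 1
        labels = ["a"] * n + ["b"] * n
        model = fit_oplsda(autoscale(X), labels, A=1, A_ortho=1)
        assert abs(model.W_pred[0, 0]) > 0.95

    def test_separable_three_class_training_accuracy(self):
        rng = np.random.default_rng(3)
        X, labels, _ = three_class_fixture(rng, sep=6.0)
        model = fit_oplsda(autoscale(X), labels, A=2, A_ortho=1)
        pred = predict_oplsda(model, X)
        assert pred.predicted_label == labels

    def test_orthogonal_scores_uncorrelated_with_dummy(self):
        rng = np.random.default_rng(4)
        X, labels, _ = three_class_fixture(rng)
        model = fit_oplsda(autoscale(X), labels, A=2, A_ortho=2)
        Y = one_hot(labels, model.class_labels)
        Yc = Y - Y.mean(axis=0)
        for a in range(model.A_ortho):
            t = model.T_ortho[:, a]
            tc = t - t.mean()
            for j in range(Y.shape[1]):
                denom = np.linalg.norm(tc) * np.linalg.norm(Yc[:, j])
                assert abs(tc @ Yc[:, j]) / denom < 1e-8

    def test_deflation_conserves_sum_of_squares(self):
        rng = np.random.default_rng(5)
        X, labels, _ = three_class_fixture(rng)
        model = fit_oplsda(autoscale(X), labels, A=2, A_ortho=2)
        assert abs(model.ss_input - model.ss_ortho - model.ss_filtered) < 1e-6 * model.ss_input

    def test_weight_columns_unit_norm(self):
        rng = np.random.default_rng(6)
        X, labels, _ = three_class_fixture(rng)
        model = fit_oplsda(autoscale(X), labels, A=2, A_ortho=1)
        assert np.allclose(np.linalg.norm(model.W_pred, axis=0), 1.0, atol=1e-9)
        assert np.allclose(np.linalg.norm(model.W_ortho, axis=0), 1.0, atol=1e-9)

    def test_small_class_rejected(self):
        X = np.random.default_rng(7).normal(0, 1, (5, 3))
        with pytest.raises(ValueError):
            fit_oplsda(autoscale(X), ["a", "a", "a", "a", "b"])

    def test_excess_components_raise_rank_error(self):
        rng = np.random.default_rng(8)
        X, labels, _ = three_class_fixture(rng)
        sc = autoscale(X)
        with pytest.raises(RankError):
            fit_oplsda(sc, labels, A=3)  # K-1 = 2
        with pytest.raises(RankError):
            fit_oplsda(sc, labels, A=2, A_ortho=4)  # only p - rank = 3 feasible

    def test_infeasible_ortho_when_classes_fill_feature_space(self):
        # 6 classes on 5 features: rank(Yc^T X) = 5 = p, no exact ortho direction
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (60, 5))
        labels = [c for c in "abcdef" for _ in range(10)]
        sc = autoscale(X)
        with pytest.raises(RankError):
            fit_oplsda(sc, labels, A_ortho=1)
        model = fit_oplsda(sc, labels)  # auto resolves to A_ortho=0
        assert model.A_ortho == 0 and model.A == 5


class TestPredict:
    def test_training_self_consistency(self):
        rng = np.random.default_rng(10)
        X, labels, _ = three_class_fixture(rng)
        model = fit_oplsda(autoscale(X), labels, A=2, A_ortho=1)
        pred = predict_oplsda(model, X)
        assert np.allclose(pred.scores_pred, model.T_pred, atol=1e-10)
        assert np.allclose(pred.scores_ortho, model.T_ortho, atol=1e-10)

    def test_class_mean_sample_predicted_as_class(self):
        rng = np.random.default_rng(11)
        X, labels, means = three_class_fixture(rng, sep=6.0)
        model = fit_oplsda(autoscale(X), labels, A=2, A_ortho=1)
        for name, mu in means.items():
            pred = predict_oplsda(model, mu[None, :])
            assert pred.predicted_label == [name]

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(12)
        X, labels, _ = three_class_fixture(rng)
        perm = rng.permutation(5)
        m1 = fit_oplsda(autoscale(X), labels, A=2, A_ortho=1)
        m2 = fit_oplsda(autoscale(X[:, perm]), labels, A=2, A_ortho=1)
        p1 = predict_oplsda(m1, X)
        p2 = predict_oplsda(m2, X[:, perm])
        assert p1.predicted_label == p2.predicted_label
        assert np.allclose(p1.predicted_Y, p2.predicted_Y, atol=1e-8)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        X, labels, _ = three_class_fixture(rng)
        mapping = {"alpha": "zeta", "beta": "eta", "gamma": "theta"}
        m1 = fit_oplsda(autoscale(X), labels, A=2, A_ortho=1)
        m2 = fit_oplsda(autoscale(X), [mapping[l] for l in labels], A=2, A_ortho=1)
        p1 = predict_oplsda(m1, X)
        p2 = predict_oplsda(m2, X)
        assert [mapping[l] for l in p1.predicted_label] == p2.predicted_label

    def test_column_count_mismatch_rejected(self):
        rng = np.random.default_rng(14)
        X, labels, _ = three_class_fixture(rng)
        model = fit_oplsda(autoscale(X), labels, A=2, A_ortho=0)
        with pytest.raises(ValueError):
            predict_oplsda(model, X[:, :3])


class TestScoresPlot:
    def test_two_predictive_components(self):
        rng = np.random.default_rng(15)
        X, labels, _ = three_class_fixture(rng)
        model = fit_oplsda(autoscale(X), labels, A=2, A_ortho=1)
        coords = scores_plot_data(model)
        assert np.allclose(coords, model.T_pred[:, :2])

    def test_fallback_to_orthogonal_score(self):
        rng = np.random.default_rng(16)
        n = 30
        X = rng.normal(0, 1, (2 * n, 5))
        X[n:, 0] += 4
        labels = ["a"] * n + ["b"] * n
        model = fit_oplsda(autoscale(X), labels, A=1, A_ortho=1)
        coords = scores_plot_data(model)
        assert np.allclose(coords[:, 1], model.T_ortho[:, 0])

    def test_class_centroids_separate(self):
        rng = np.random.default_rng(17)
        X, labels, _ = three_class_fixture(rng, sep=6.0)
        model = fit_oplsda(autoscale(X), labels, A=2, A_ortho=1)
        coords = scores_plot_data(model)
        lab = np.array(labels)
        cents = [coords[lab == c].mean(axis=0) for c in sorted(set(labels))]
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(cents[i] - cents[j]) > 1.0


class TestModelIO:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(18)
        X, labels, _ = three_class_fixture(rng)
        model = fit_oplsda(autoscale(X), labels, A=2, A_ortho=1)
        save_model(model, tmp_path / "model.json")
        back = load_model(tmp_path / "model.json")
        p1 = predict_oplsda(model, X)
        p2 = predict_oplsda(back, X)
        assert p1.predicted_label == p2.predicted_label
        assert np.allclose(p1.predicted_Y, p2.predicted_Y, atol=1e-12)
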