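"""LDA classifier, stepwise (Wilks) pre-selection, and greedy forward LDA."""

import numpy as np
import pytest

from featureforge.selection import (
    FeatureMatrix,
    SelectionTrace,
    fit_lda,
    greedy_lda_select,
    lda_accuracy,
    predict_lda,
    sda_select,
    selection_curve,
    standardize_impute,
)
from featureforge.synthetic import PlantedFeatureSpec, gen_planted_features


def two_gaussians(n=200, gap=10.0, sd=0.1, seed=0, d=1):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-gap / 2, sd, size=(n // 2, d)),
                   rng.normal(gap / 2, sd, size=(n // 2, d))])
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    return X, y


class TestLda:
    def test_separable_classes_reach_perfect_training_accuracy(self):
        X, y = two_gaussians()
        model = fit_lda(X, y)
        assert np.mean(predict_lda(model, X) == y) == 1.0

    def test_two_class_direction_matches_closed_form_fisher(self):
        rng = np.random.default_rng(1)
        n, d = 500, 4
        y = np.array(["a"] * n + ["b"] * n)
        X = rng.normal(size=(2 * n, d))
        X[n:] += np.array([1.0, 0.5, -0.3, 0.2])
        model = fit_lda(X, y, ridge=0.0)
        w_model = model.coef[1] - model.coef[0]
        # closed form: Sigma^-1 (mu_b - mu_a) with pooled covariance
        mu_a, mu_b = X[:n].mean(0), X[n:].mean(0)
        resid = np.vstack([X[:n] - mu_a, X[n:] - mu_b])
        sigma = resid.T @ resid / (2 * n - 2)
        w_ref = np.linalg.solve(sigma, mu_b - mu_a)
        cos = w_model @ w_ref / (np.linalg.norm(w_model) * np.linalg.norm(w_ref))
        assert cos > 1 - 1e-8

    def test_agrees_with_sklearn_reference(self):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis").LinearDiscriminantAnalysis
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 5))
        y = rng.integers(0, 4, size=400).astype(str)
        for c in range(4):
            X[y == str(c), c % 5] += 2.0
        ours = predict_lda(fit_lda(X, y, ridge=0.0), X)
        ref = sklearn_lda().fit(X, y).predict(X)
        assert np.mean(ours == ref) == 1.0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 3))
        y = rng.integers(0, 3, 100).astype(str)
        X[y == "0"] += 1
        m1 = fit_lda(X, y)
        perm = rng.permutation(100)
        m2 = fit_lda(X[perm], y[perm])
        assert np.allclose(m1.coef, m2.coef, atol=1e-10)
        assert np.allclose(m1.intercept, m2.intercept, atol=1e-10)

    def test_point_at_class_mean_predicted_as_that_class(self):
        X, y = two_gaussians()
        model = fit_lda(X, y)
        # equalize priors so the test isolates the mean term
        model.log_priors[:] = np.log(0.5)
        model.__post_init__()
        for g, cls in enumerate(model.classes):
            assert predict_lda(model, model.means[[g]])[0] == cls

    def test_scores_argmax_invariant_under_constant_shift(self):
        X, y = two_gaussians(seed=4)
        model = fit_lda(X, y)
        labels, scores = predict_lda(model, X, return_scores=True)
        shifted = scores + 7.5
        assert np.array_equal(np.argmax(scores, 1), np.argmax(shifted, 1))

    def test_dimension_mismatch_raises(self):
        X, y = two_gaussians()
        model = fit_lda(X, y)
        with pytest.raises(ValueError):
            predict_lda(model, np.zeros((3, 5)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((10, 2)), np.array(["a"] * 10))


class TestStandardizeImpute:
    def test_missing_values_land_on_column_mean(self):
        X = np.array([[1.0, np.nan], [3.0, 4.0], [5.0, 8.0]])
        Z = standardize_impute(X)
        assert np.isfinite(Z).all()
        assert Z[0, 1] == 0.0  # imputed at the standardized mean

    def test_observed_entries_standardized(self):
        rng = np.random.default_rng(5)
        X = rng.normal(3, 2, size=(1000, 3))
        Z = standardize_impute(X)
        assert np.allclose(Z.mean(0), 0, atol=1e-12)
        assert np.allclose(Z.std(0), 1, atol=1e-12)


class TestSdaSelect:
    def test_duplicated_column_never_selected_twice(self):
        fm, info = gen_planted_features(PlantedFeatureSpec(
            n_rows=1000, n_informative=2, n_noise=10, seed=0))
        X = np.hstack([fm.X, fm.X[:, [info[0]]]])  # exact duplicate
        dup = X.shape[1] - 1
        kept = sda_select(X, fm.y)
        assert not (info[0] in kept and dup in kept)

    def test_informative_columns_selected_on_planted_design(self):
        fm, info = gen_planted_features(PlantedFeatureSpec(
            n_rows=2000, n_informative=3, n_noise=20, seed=1))
        kept = sda_select(standardize_impute(fm.X), fm.y)
        assert set(info) <= set(kept)

    def test_single_class_returns_empty_with_warning(self):
        with pytest.warns(UserWarning, match="single-class"):
            out = sda_select(np.random.default_rng(0).normal(size=(20, 3)),
                             np.array(["a"] * 20))
        assert out == []

    def test_constant_column_skipped_with_warning(self):
        fm, _ = gen_planted_features(PlantedFeatureSpec(
            n_rows=500, n_informative=2, n_noise=5, seed=2))
        X = np.hstack([fm.X, np.ones((500, 1))])
        with pytest.warns(UserWarning, match="constant"):
            kept = sda_select(X, fm.y)
        assert X.shape[1] - 1 not in kept

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            sda_select(np.zeros((10, 2)), np.array(["a", "b"] * 5),
                       f_enter=1.0, f_remove=2.0)


class TestGreedySelect:
    def test_dominating_column_chosen_first_and_trace_short(self):
        rng = np.random.default_rng(6)
        n = 400
        y = rng.integers(0, 2, n).astype(str)
        X = rng.normal(size=(n, 5)) * 0.01
        X[:, 3] = np.where(y == "0", -5.0, 5.0) + rng.normal(0, 0.01, n)
        trace = greedy_lda_select(X, y, seed=0)
        assert trace.chosen[0] == 3
        assert trace.cumulative_accuracy[0] == 1.0
        assert len(trace.chosen) == 1

    def test_cumulative_accuracy_non_decreasing(self):
        fm, _ = gen_planted_features(PlantedFeatureSpec(seed=3))
        trace = greedy_lda_select(standardize_impute(fm.X), fm.y, seed=3)
        cum = trace.cumulative_accuracy
        assert all(b >= a for a, b in zip(cum, cum[1:]))
        assert all(g > 0 for g in trace.marginal_gain)

    def test_stop_gain_rule_halts_on_constructed_marginal_gains(self):
        # accuracy oracle with known best-subset gains per added column:
        # 0.5, 0.01, 0.001 then 0.00001 (< 5e-5) for every further column
        gains = {0: 0.5, 1: 0.01, 2: 0.001}

        def score(cols):
            return sum(gains.get(c, 0.00001) for c in cols)

        X = np.zeros((10, 6))
        y = np.array(["a", "b"] * 5)
        trace = greedy_lda_select(X, y, stop_gain=5e-5, score_fn=score)
        assert trace.chosen == [0, 1, 2]
        assert trace.stop_reason == "gain_below_threshold"
        assert trace.marginal_gain == pytest.approx([0.5, 0.01, 0.001])

    def test_trace_internally_consistent_with_refits(self):
        fm, _ = gen_planted_features(PlantedFeatureSpec(
            n_rows=800, n_informative=3, n_noise=10, seed=4))
        X = standardize_impute(fm.X)
        trace = greedy_lda_select(X, y := fm.y, seed=4)
        # recompute each cumulative accuracy by refitting on the same split
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(y))
        n_eval = int(round(0.2 * len(y)))
        ev, ft = perm[:n_eval], perm[n_eval:]
        for k in range(1, len(trace.chosen) + 1):
            cols = trace.chosen[:k]
            acc = lda_accuracy(X[np.ix_(ft, cols)], y[ft], X[np.ix_(ev, cols)], y[ev])
            assert acc == pytest.approx(trace.cumulative_accuracy[k - 1])

    def test_greedy_never_below_sda_alone_on_fixture(self):
        fm, _ = gen_planted_features(PlantedFeatureSpec(seed=5))
        X = standardize_impute(fm.X)
        kept = sda_select(X, fm.y)
        trace = greedy_lda_select(X[:, kept], fm.y, seed=5)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(fm.y))
        n_eval = int(round(0.2 * len(fm.y)))
        ev, ft = perm[:n_eval], perm[n_eval:]
        full_acc = lda_accuracy(X[np.ix_(ft, kept)], fm.y[ft],
                                X[np.ix_(ev, kept)], fm.y[ev])
        assert trace.cumulative_accuracy[-1] >= full_acc - 1e-9


class TestSelectionCurve:
    def test_differencing(self):
        trace = SelectionTrace(chosen=[0, 1, 2],
                               cumulative_accuracy=[0.5, 0.6, 0.6],
                               marginal_gain=[0.5, 0.1, 0.0],
                               stop_reason="max_k_reached")
        curve = selection_curve(trace)
        assert curve["marginal_gain"] == [0.5, 0.1, 0.0]

    def test_threshold_ks(self):
        trace = SelectionTrace(chosen=[0, 1, 2, 3],
                               cumulative_accuracy=[0.90, 0.94, 0.949, 0.95],
                               marginal_gain=[0.90, 0.04, 0.009, 0.001],
                               stop_reason="max_k_reached")
        curve = selection_curve(trace)
        # 0.95 * 0.95 = 0.9025 -> first k with cum >= 0.9025 is k=2
        assert curve["k95"] == 2
        # 0.99 * 0.95 = 0.9405 -> k=3
        assert curve["k99"] == 3

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            selection_curve(SelectionTrace([], [], [], "none"))

    def test_inconsistent_gains_rejected(self):
        with pytest.raises(ValueError):
            SelectionTrace(chosen=[0], cumulative_accuracy=[0.5],
                           marginal_gain=[0.4], stop_reason="x")


def test_feature_matrix_shape_validation():
    with pytest.raises(ValueError):
        FeatureMatrix(X=np.zeros((5, 2)), y=np.zeros(4))
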