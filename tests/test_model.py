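import math

import numpy as np
import pytest

from oracles import counting_final_scores, grid_search_logistic

from rmlm.features import FeatureTable, PairIndex
from rmlm.model import (
    FitDivergedError,
    TrainingSet,
    WeightVector,
    final_scores,
    fit_weights,
    log_likelihood,
    posterior,
    read_model,
    write_model,
)


def make_ts(x: np.ndarray, y) -> TrainingSet:
    x = np.atleast_2d(x)
    pairs = PairIndex(tuple((r, 0) for r in range(x.shape[0])))
    cols = tuple(f"f{c}" for c in range(x.shape[1]))
    return TrainingSet(FeatureTable(pairs, cols, x), np.asarray(y, dtype=float))


class TestPosterior:
    def test_zero_logit_is_half(self):
        w = WeightVector(np.zeros(2))
        assert posterior(np.array([0.4, 0.6]), w) == pytest.approx(0.5)

    def test_closed_form_value(self):
        w = WeightVector(np.array([math.log(3.0)]))
        assert posterior(np.array([1.0]), w) == pytest.approx(0.75)

    def test_no_overflow_at_extreme_logits(self):
        w = WeightVector(np.array([1000.0]))
        p = posterior(np.array([1.0]), w)
        assert 0.0 < p <= 1.0 and np.isfinite(p)

    def test_complement_sums_to_one(self):
        w = WeightVector(np.array([2.0, -1.0]))
        phi = np.array([0.3, 0.9])
        p1 = posterior(phi, w)
        p0 = 1.0 / (1.0 + math.exp(w.weights @ phi))
        assert p1 + p0 == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            posterior(np.array([1.0, 2.0]), WeightVector(np.array([1.0])))


class TestLogLikelihood:
    def test_zero_weights_give_n_log_half(self):
        ts = make_ts(np.random.default_rng(0).random((7, 2)), [1, 0, 1, 1, 0, 0, 1])
        ll = log_likelihood(WeightVector(np.zeros(2), ridge=0.0), ts)
        assert ll == pytest.approx(7 * math.log(0.5))

    def test_single_observation_closed_form(self):
        ts = make_ts(np.array([[1.0]]), [1])
        ll = log_likelihood(WeightVector(np.array([math.log(3.0)]), ridge=0.0), ts)
        assert ll == pytest.approx(math.log(0.75))

    @pytest.mark.parametrize("seed", range(5))
    def test_midpoint_concavity(self, seed):
        rng = np.random.default_rng(seed)
        ts = make_ts(rng.random((20, 3)), rng.integers(0, 2, 20))
        w1, w2 = rng.normal(size=(2, 3)) * 3
        mid = WeightVector((w1 + w2) / 2, ridge=0.0)
        lhs = log_likelihood(mid, ts)
        rhs = 0.5 * (log_likelihood(WeightVector(w1, ridge=0.0), ts)
                     + log_likelihood(WeightVector(w2, ridge=0.0), ts))
        assert lhs >= rhs - 1e-12


class TestFitWeights:
    def test_symmetric_dataset_yields_zero(self):
        ts = make_ts(np.array([[1.0], [1.0], [-1.0], [-1.0]]), [1, 0, 1, 0])
        w = fit_weights(ts, ridge=0.0)
        np.testing.assert_allclose(w.weights, 0.0, atol=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((30, 2)) * 2 - 1
        true = np.array([1.0, -1.5])
        y = rng.random(30) < 1.0 / (1.0 + np.exp(-x @ true))
        ts = make_ts(x, y.astype(float))
        fitted = fit_weights(ts, ridge=0.01, tol=1e-8)
        oracle = grid_search_logistic(x, y.astype(float), ridge=0.01)
        assert np.abs(oracle).max() < 4.5
        np.testing.assert_allclose(fitted.weights, oracle, atol=0.02)

    def test_gradient_norm_at_solution(self):
        rng = np.random.default_rng(5)
        x = rng.random((50, 3))
        y = rng.integers(0, 2, 50).astype(float)
        ts = make_ts(x, y)
        w = fit_weights(ts, ridge=1e-4, tol=1e-8)
        # finite-difference gradient of the penalised log likelihood
        eps = 1e-6
        for k in range(3):
            up, down = w.weights.copy(), w.weights.copy()
            up[k] += eps
            down[k] -= eps
            g = (log_likelihood(WeightVector(up, ridge=1e-4), ts)
                 - log_likelihood(WeightVector(down, ridge=1e-4), ts)) / (2 * eps)
            assert abs(g) < 1e-5

    def test_separable_data_flagged_without_ridge(self):
        x = np.array([[1.0], [2.0], [-1.0], [-2.0]])
        y = [1, 1, 0, 0]
        with pytest.raises(FitDivergedError):
            fit_weights(make_ts(x, y), ridge=0.0, max_iter=60)
        w = fit_weights(make_ts(x, y), ridge=0.01)
        assert np.isfinite(w.weights).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_weights(make_ts(np.ones((3, 1)), [1, 1, 1]))

    def test_fit_beats_zero_and_random_perturbations(self):
        rng = np.random.default_rng(11)
        x = rng.random((100, 3))
        y = (rng.random(100) < 1.0 / (1.0 + np.exp(-(x @ [2.0, -1.0, 0.5])))).astype(float)
        ts = make_ts(x, y)
        w = fit_weights(ts, ridge=1e-4)
        best = log_likelihood(w, ts)
        assert best >= log_likelihood(WeightVector(np.zeros(3), ridge=1e-4), ts)
        for _ in range(100):
            perturbed = WeightVector(
                w.weights + rng.normal(scale=0.1, size=3), ridge=1e-4)
            assert best >= log_likelihood(perturbed, ts) - 1e-12

    def test_agrees_with_sklearn_ridge_logistic(self):
        # independent cross-check: sklearn minimises the same penalised
        # objective with C = 1 / ridge and no intercept
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(21)
        x = rng.random((200, 4))
        y = (rng.random(200) < 1.0 / (1.0 + np.exp(-(x @ [3.0, -2.0, 0.0, 1.0])))).astype(float)
        ridge = 0.1
        ours = fit_weights(make_ts(x, y), ridge=ridge, tol=1e-10)
        ref = LogisticRegression(C=1.0 / ridge, fit_intercept=False,
                                 tol=1e-10, max_iter=1000)
        ref.fit(x, y)
        np.testing.assert_allclose(ours.weights, ref.coef_.ravel(), atol=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_parameter_recovery_on_independent_features(self, seed):
        # labels generated from the logistic model itself must give the
        # weight direction back at moderate sample size
        rng = np.random.default_rng(seed)
        true = np.array([4.0, -3.0, 2.0])
        x = rng.random((2000, 3))
        y = (rng.random(2000) < 1.0 / (1.0 + np.exp(-(x @ true)))).astype(float)
        w = fit_weights(make_ts(x, y), ridge=1e-4)
        cos = w.weights @ true / np.linalg.norm(w.weights) / np.linalg.norm(true)
        assert cos >= 0.9


class TestFinalScores:
    def test_strictly_ordered_posteriors(self):
        np.testing.assert_allclose(
            final_scores([0.2, 0.5, 0.9]), [1 / 3, 2 / 3, 1.0])

    def test_all_ties_share_the_top(self):
        np.testing.assert_allclose(final_scores([0.4] * 5), 1.0)

    def test_maximum_is_always_one(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            q = final_scores(rng.random(int(rng.integers(1, 30))))
            assert q.max() == 1.0 and q.min() >= 1.0 / len(q)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_counting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.choice([0.1, 0.2, 0.5, 0.9], size=12)
        np.testing.assert_allclose(final_scores(p), counting_final_scores(p))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        p = rng.random(40)
        np.testing.assert_allclose(final_scores(p), final_scores(np.exp(3 * p)))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            final_scores([])


def test_model_file_roundtrip(tmp_path):
    w = WeightVector(np.array([0.5, -1.25, 3.0]), ridge=0.01,
                     feature_labels=("a", "b", "c"))
    path = tmp_path / "model.txt"
    write_model(w, str(path))
    back = read_model(str(path))
    np.testing.assert_array_equal(back.weights, w.weights)
    assert back.ridge == w.ridge
    assert back.feature_labels == w.feature_labels
    assert back.include_bias == w.include_bias
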