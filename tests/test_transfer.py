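import math

import numpy as np
import pytest

from fusemap.transfer import (
    BoostState,
    DomainAdaptedModel,
    ElasticNetParams,
    TransferParams,
    boost_round,
    fit_elastic_net,
    tradaboost_fit,
    tradaboost_predict,
    weighted_median,
)


class TestFitElasticNet:
    def test_alpha_zero_matches_least_squares(self, rng):
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.5, -2.0, 0.5]) + 0.7 + rng.normal(0, 0.1, 60)
        est = fit_elastic_net(X, y, params=ElasticNetParams(alpha=0.0))
        A = np.column_stack([np.ones(60), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        assert est.intercept == pytest.approx(beta[0], abs=1e-8)
        assert np.allclose(est.coef, beta[1:], atol=1e-8)

    def test_constant_target_gives_intercept_only(self, rng):
        X = rng.normal(size=(20, 4))
        est = fit_elastic_net(X, np.full(20, 3.3))
        assert np.all(est.coef == 0)
        assert est.intercept == pytest.approx(3.3)

    def test_zero_weight_points_ignored(self, rng):
        X = rng.normal(size=(40, 2))
        y = X @ np.array([2.0, -1.0])
        w = np.ones(40)
        # corrupt 5 points but give them zero weight
        y2 = y.copy()
        y2[:5] += 100.0
        w2 = w.copy()
        w2[:5] = 0.0
        p = ElasticNetParams(alpha=0.0)
        est_clean = fit_elastic_net(X[5:], y[5:], params=p)
        est_weighted = fit_elastic_net(X, y2, w2, p)
        assert np.allclose(est_weighted.coef, est_clean.coef, atol=1e-8)

    def test_penalty_shrinks_coefficients(self, rng):
        X = rng.normal(size=(80, 3))
        y = X @ np.array([3.0, 3.0, 3.0]) + rng.normal(0, 0.5, 80)
        c0 = fit_elastic_net(X, y, params=ElasticNetParams(alpha=0.0)).coef
        c1 = fit_elastic_net(X, y, params=ElasticNetParams(alpha=1.0)).coef
        assert np.linalg.norm(c1) < np.linalg.norm(c0)

    def test_invalid_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        with pytest.raises(ValueError, match="non-finite"):
            fit_elastic_net(np.where(X > 2, np.nan, X) * np.nan, y)
        with pytest.raises(ValueError, match="weights"):
            fit_elastic_net(X, y, -np.ones(10))
        with pytest.raises(ValueError):
            ElasticNetParams(l1_ratio=1.5)
        with pytest.raises(ValueError):
            ElasticNetParams(alpha=-1.0)


class TestWeightedMedian:
    def test_dominant_first_weight(self):
        preds = np.array([[1.0, 2.0, 3.0]])
        assert weighted_median(preds, np.array([0.7, 0.2, 0.1]))[0] == 1.0

    def test_equal_weights_even_count_lower_middle(self):
        preds = np.array([[1.0, 2.0, 3.0, 4.0]])
        assert weighted_median(preds, np.full(4, 0.25))[0] == 2.0

    def test_equal_weights_odd_count_is_median(self):
        preds = np.array([[5.0, 1.0, 3.0]])
        assert weighted_median(preds, np.ones(3))[0] == 3.0

    def test_single_estimator_identity(self, rng):
        preds = rng.normal(size=(7, 1))
        assert np.allclose(weighted_median(preds, np.array([2.0])), preds.ravel())

    def test_between_min_and_max(self, rng):
        preds = rng.normal(size=(30, 5))
        w = rng.random(5) + 0.1
        med = weighted_median(preds, w)
        assert np.all(med >= preds.min(axis=1)) and np.all(med <= preds.max(axis=1))

    def test_invariant_to_weight_scaling(self, rng):
        preds = rng.normal(size=(10, 4))
        w = rng.random(4) + 0.1
        assert np.allclose(weighted_median(preds, w), weighted_median(preds, 13.0 * w))


class TestBoostState:
    def test_initial_state(self):
        st = BoostState.initial(n_source=3, n_target=2, n_boost=10)
        assert np.allclose(st.weights, 0.2)
        assert st.is_target.tolist() == [False, False, False, True, True]
        assert st.beta_source == pytest.approx(1.0 / (1.0 + math.sqrt(2 * math.log(3) / 10)))

    def test_no_source_beta_is_one(self):
        st = BoostState.initial(0, 4, 10)
        assert st.beta_source == 1.0

    def test_too_few_targets_rejected(self):
        with pytest.raises(ValueError, match="target"):
            BoostState.initial(5, 1, 10)


class TestBoostRound:
    def test_hand_computed_update(self):
        # 2 source + 2 target, residuals [2, 4, 1, 1]
        st = BoostState.initial(2, 2, 4)
        y = np.zeros(4)
        preds = np.array([2.0, 4.0, 1.0, 1.0])
        nxt = boost_round(st, preds, y)

        e = np.array([0.5, 1.0, 0.25, 0.25])
        eps = (0.25 * 0.25 + 0.25 * 0.25) / 0.5
        assert nxt.epsilons[-1] == pytest.approx(eps)
        beta_t = eps / (1 - eps)
        assert nxt.betas[-1] == pytest.approx(beta_t)
        w = np.array(
            [
                0.25 * st.beta_source ** e[0],
                0.25 * st.beta_source ** e[1],
                0.25 * beta_t ** (-e[2]),
                0.25 * beta_t ** (-e[3]),
            ]
        )
        assert np.allclose(nxt.weights, w / w.sum(), atol=1e-12)
        assert not nxt.finished

    def test_weights_stay_on_simplex(self, rng):
        st = BoostState.initial(10, 5, 10)
        y = rng.normal(size=15)
        for _ in range(8):
            st = boost_round(st, y + rng.normal(0, 1, 15), y)
            assert st.weights.sum() == pytest.approx(1.0)
            assert np.all(st.weights >= 0)

    def test_target_mass_never_decreases(self, rng):
        st = BoostState.initial(20, 8, 10)
        y = rng.normal(size=28)
        for _ in range(6):
            prev = st.weights[st.is_target].sum()
            st = boost_round(st, y + rng.normal(0, 1, 28), y)
            assert st.weights[st.is_target].sum() >= prev - 1e-12

    def test_high_target_error_caps_beta_at_one(self):
        st = BoostState.initial(2, 2, 4)
        # max residual sits on a target instance: target errors dominate
        preds = np.array([0.5, 0.5, 4.0, 4.0])
        nxt = boost_round(st, preds, np.zeros(4))
        assert nxt.betas[-1] == 1.0
        # target weights untouched before renormalization (beta_t ** 0 rule)
        assert nxt.weights[2] == nxt.weights[3]
        assert not nxt.finished

    def test_perfect_fit_finishes_with_max_estimator_weight(self):
        st = BoostState.initial(2, 2, 4)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        nxt = boost_round(st, y.copy(), y)
        assert nxt.finished
        assert nxt.betas[-1] == pytest.approx(1e-10)
        assert np.allclose(nxt.weights, st.weights)

    def test_zero_target_error_with_source_error_finishes(self):
        st = BoostState.initial(2, 2, 4)
        preds = np.array([1.0, 2.0, 0.0, 0.0])
        nxt = boost_round(st, preds, np.zeros(4))
        assert nxt.finished
        assert nxt.epsilons[-1] == 0.0
        # source instances with error were still down-weighted
        assert nxt.weights[1] < nxt.weights[2]


class TestTradaboost:
    def make_problem(self, seed=0, n_src=120, n_tgt=40, shift=0.0):
        rng = np.random.default_rng(seed)
        w = np.array([2.0, -1.0, 0.5])
        Xs = rng.normal(size=(n_src, 3))
        Xt = rng.normal(size=(n_tgt, 3)) + shift
        ys = Xs @ w + rng.normal(0, 0.1, n_src)
        yt = Xt @ w + rng.normal(0, 0.1, n_tgt)
        return Xs, ys, Xt, yt

    def test_recovers_linear_signal(self):
        Xs, ys, Xt, yt = self.make_problem()
        model = tradaboost_fit(Xs, ys, Xt, yt, en=ElasticNetParams(alpha=0.01))
        rng = np.random.default_rng(1)
        Xnew = rng.normal(size=(50, 3))
        ynew = Xnew @ np.array([2.0, -1.0, 0.5])
        pred = tradaboost_predict(model, Xnew)
        assert np.corrcoef(pred, ynew)[0, 1] > 0.98

    def test_keeps_last_half_of_rounds(self):
        Xs, ys, Xt, yt = self.make_problem()
        tp = TransferParams(n_boost=9)
        model = tradaboost_fit(Xs, ys, Xt, yt, tp=tp)
        assert len(model.estimators) <= math.ceil(9 / 2)
        assert len(model.estimator_weights) == len(model.estimators)

    def test_deterministic(self):
        Xs, ys, Xt, yt = self.make_problem(seed=3)
        m1 = tradaboost_fit(Xs, ys, Xt, yt)
        m2 = tradaboost_fit(Xs, ys, Xt, yt)
        assert m1.to_json() == m2.to_json()

    def test_empty_source_reduces_to_target_boosting(self):
        _, _, Xt, yt = self.make_problem(n_tgt=80)
        model = tradaboost_fit([], [], Xt, yt, en=ElasticNetParams(alpha=0.01))
        pred = tradaboost_predict(model, Xt)
        assert np.corrcoef(pred, yt)[0, 1] > 0.95

    def test_json_round_trip_predicts_identically(self):
        Xs, ys, Xt, yt = self.make_problem(seed=5)
        model = tradaboost_fit(Xs, ys, Xt, yt)
        back = DomainAdaptedModel.from_json(model.to_json())
        assert np.allclose(tradaboost_predict(back, Xt), tradaboost_predict(model, Xt))

    def test_feature_name_mismatch_rejected(self):
        Xs, ys, Xt, yt = self.make_problem()
        model = tradaboost_fit(Xs, ys, Xt, yt, feature_names=["a", "b", "c"])
        with pytest.raises(ValueError, match="mismatch"):
            tradaboost_predict(model, Xt, feature_names=["a", "b", "z"])

    def test_shape_validation(self):
        Xs, ys, Xt, yt = self.make_problem()
        with pytest.raises(ValueError, match="rows"):
            tradaboost_fit(Xs, ys[:-1], Xt, yt)
        with pytest.raises(ValueError, match="feature columns"):
            tradaboost_fit(Xs[:, :2], ys, Xt, yt)
        with pytest.raises(ValueError, match="n_target"):
            tradaboost_fit(Xs, ys, Xt[:1], yt[:1])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TransferParams(n_boost=1)
        with pytest.raises(ValueError):
            TransferParams(loss="cubic")
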