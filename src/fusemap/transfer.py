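"""Instance-weighted transfer boosting (TrAdaBoostR2) with elastic-net base
learners.

A source cohort and a (smaller) target-adaptation cohort are pooled; at each
boosting round an elastic net is fitted under the current instance weights,
poorly predicted source instances are down-weighted and poorly predicted
target instances up-weighted, shifting importance towards the target domain.
Prediction is the weighted median over the estimators kept from the last
ceil(N/2) rounds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, LinearRegression

__all__ = [
    "ElasticNetParams",
    "TransferParams",
    "BoostState",
    "LinearPredictor",
    "DomainAdaptedModel",
    "fit_elastic_net",
    "boost_round",
    "tradaboost_fit",
    "tradaboost_predict",
]

_EPS_BETA = 1e-10


@dataclass
class ElasticNetParams:
    """Defaults follow the out-of-the-box elastic-net configuration:
    l1_ratio = 0.5 (balanced L1/L2) and alpha = 1.0 (overall penalty)."""

    l1_ratio: float = 0.5
    alpha: float = 1.0
    fit_intercept: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.l1_ratio <= 1.0):
            raise ValueError("l1_ratio must be in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


@dataclass
class TransferParams:
    """n_boost : boosting rounds N (weighted median uses the last ceil(N/2)).
    loss : adjusted-error shape over |residual| / max |residual|."""

    n_boost: int = 10
    loss: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boost < 2:
            raise ValueError("n_boost must be >= 2")
        if self.loss not in ("linear", "square", "exponential"):
            raise ValueError("loss must be linear, square or exponential")


@dataclass
class LinearPredictor:
    coef: np.ndarray
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept


def fit_elastic_net(X, y, sample_weights=None, params: ElasticNetParams | None = None) -> LinearPredictor:
    """Weighted elastic net; alpha = 0 falls back to ordinary least squares."""
    params = params or ElasticNetParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be 2-D with at least one feature")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    if sample_weights is not None:
        sample_weights = np.asarray(sample_weights, dtype=float)
        if np.any(sample_weights < 0) or sample_weights.sum() <= 0:
            raise ValueError("sample weights must be nonnegative with positive sum")
    if np.ptp(y) == 0:
        w = sample_weights if sample_weights is not None else np.ones_like(y)
        return LinearPredictor(np.zeros(X.shape[1]), float(np.average(y, weights=w)))
    if params.alpha == 0:
        est = LinearRegression(fit_intercept=params.fit_intercept)
    else:
        est = ElasticNet(
            alpha=params.alpha,
            l1_ratio=params.l1_ratio,
            fit_intercept=params.fit_intercept,
            max_iter=10000,
        )
    est.fit(X, y, sample_weight=sample_weights)
    return LinearPredictor(np.asarray(est.coef_, dtype=float).ravel(), float(est.intercept_))


@dataclass
class BoostState:
    """Instance weights on the probability simplex plus per-round bookkeeping."""

    weights: np.ndarray
    is_target: np.ndarray
    beta_source: float
    loss: str = "linear"
    epsilons: list = field(default_factory=list)
    betas: list = field(default_factory=list)
    finished: bool = False

    @classmethod
    def initial(cls, n_source: int, n_target: int, n_boost: int, loss: str = "linear") -> "BoostState":
        n = n_source + n_target
        if n_target < 2:
            raise ValueError("at least 2 target instances required")
        beta_s = 1.0 / (1.0 + math.sqrt(2.0 * math.log(n_source) / n_boost)) if n_source > 0 else 1.0
        return cls(
            weights=np.full(n, 1.0 / n),
            is_target=np.concatenate([np.zeros(n_source, bool), np.ones(n_target, bool)]),
            beta_source=beta_s,
            loss=loss,
        )


def _adjusted_errors(predictions, y, loss: str) -> np.ndarray:
    resid = np.abs(np.asarray(predictions, float) - np.asarray(y, float))
    mx = resid.max()
    if mx == 0:
        return np.zeros_like(resid)
    e = resid / mx
    if loss == "square":
        e = e**2
    elif loss == "exponential":
        e = 1.0 - np.exp(-e)
    return e


def boost_round(state: BoostState, predictions, y) -> BoostState:
    """One reverse-boosting weight update.

    Adjusted errors e_i = |resid| / max |resid|; target error rate
    eps = sum_target(w e) / sum_target(w); source weights shrink by
    beta_source^e, target weights grow by beta_t^{-e}; renormalize.
    eps >= 0.5 caps beta_t at 1 (zero estimator weight); all-zero errors end
    boosting with the current estimator carrying maximal weight.
    """
    e = _adjusted_errors(predictions, y, state.loss)
    w = state.weights
    tgt = state.is_target
    if np.all(e == 0):
        eps = 0.0
        beta_t = _EPS_BETA
        new_w = w.copy()
        finished = True
    else:
        wt = w[tgt]
        eps = float(np.sum(wt * e[tgt]) / np.sum(wt))
        finished = False
        if eps >= 0.5:
            beta_t = 1.0
        elif eps == 0.0:
            beta_t = _EPS_BETA
            finished = True
        else:
            beta_t = eps / (1.0 - eps)
        new_w = w.copy()
        new_w[~tgt] = w[~tgt] * state.beta_source ** e[~tgt]
        new_w[tgt] = w[tgt] * beta_t ** (-e[tgt])
    new_w = new_w / new_w.sum()
    return BoostState(
        weights=new_w,
        is_target=state.is_target,
        beta_source=state.beta_source,
        loss=state.loss,
        epsilons=state.epsilons + [eps],
        betas=state.betas + [beta_t],
        finished=finished,
    )


@dataclass
class DomainAdaptedModel:
    """Frozen ensemble mapping standardized raw features to the first brain
    embedding score."""

    estimators: list
    estimator_weights: np.ndarray
    feature_names: list[str]
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "estimators": [
                    {"coef": est.coef.tolist(), "intercept": est.intercept}
                    for est in self.estimators
                ],
                "estimator_weights": self.estimator_weights.tolist(),
                "feature_names": self.feature_names,
                "feature_mean": self.feature_mean.tolist(),
                "feature_sd": self.feature_sd.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DomainAdaptedModel":
        d = json.loads(text)
        return cls(
            estimators=[
                LinearPredictor(np.asarray(e["coef"], float), float(e["intercept"]))
                for e in d["estimators"]
            ],
            estimator_weights=np.asarray(d["estimator_weights"], float),
            feature_names=list(d["feature_names"]),
            feature_mean=np.asarray(d["feature_mean"], float),
            feature_sd=np.asarray(d["feature_sd"], float),
        )


def _check_columns(feature_names, expected):
    if list(feature_names) != list(expected):
        missing = [c for c in expected if c not in feature_names]
        extra = [c for c in feature_names if c not in expected]
        raise ValueError(
            f"feature columns mismatch (missing {missing[:5]}, unexpected {extra[:5]}, "
            "order must match training)"
        )


def tradaboost_fit(
    X_source,
    y_source,
    X_target,
    y_target,
    feature_names=None,
    en: ElasticNetParams | None = None,
    tp: TransferParams | None = None,
) -> DomainAdaptedModel:
    """Fit the reverse-boosted elastic-net ensemble on pooled source+target
    data. An empty source reduces the procedure to boosting on the target
    alone."""
    en = en or ElasticNetParams()
    tp = tp or TransferParams()
    X_target = np.asarray(X_target, float)
    y_source = np.asarray(y_source, float).ravel()
    y_target = np.asarray(y_target, float).ravel()
    X_source = np.asarray(X_source, float)
    if X_source.size == 0:
        X_source = np.empty((0, X_target.shape[1]))
    if X_source.shape[0] != len(y_source):
        raise ValueError("X_source rows must match y_source length")
    if X_source.size and X_source.shape[1] != X_target.shape[1]:
        raise ValueError(
            f"source has {X_source.shape[1]} feature columns, target {X_target.shape[1]}"
        )
    if len(y_target) < 2:
        raise ValueError("n_target must be >= 2")

    X = np.vstack([X_source, X_target])
    y = np.concatenate([y_source, y_target])
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mean) / sd

    state = BoostState.initial(len(y_source), len(y_target), tp.n_boost, tp.loss)
    estimators, betas = [], []
    for _ in range(tp.n_boost):
        est = fit_elastic_net(Xs, y, state.weights, en)
        state = boost_round(state, est.predict(Xs), y)
        estimators.append(est)
        betas.append(state.betas[-1])
        if state.finished:
            break

    n_run = len(estimators)
    keep = math.ceil(n_run / 2)
    kept = estimators[-keep:]
    kept_betas = np.asarray(betas[-keep:], float)
    wts = np.log(1.0 / np.maximum(kept_betas, _EPS_BETA))
    if np.all(wts <= 0):
        wts = np.ones_like(wts)  # all rounds failed (eps >= 0.5): fall back to equal votes
    return DomainAdaptedModel(
        estimators=kept,
        estimator_weights=wts,
        feature_names=list(feature_names),
        feature_mean=mean,
        feature_sd=sd,
    )


def tradaboost_predict(model: DomainAdaptedModel, X_new, feature_names=None) -> np.ndarray:
    """Weighted median of the kept estimators' predictions: sort a subject's
    predictions ascending and take the first whose cumulative estimator
    weight reaches half the total."""
    if feature_names is not None:
        _check_columns(feature_names, model.feature_names)
    X = np.asarray(X_new, float)
    if X.shape[1] != len(model.feature_names):
        raise ValueError("X_new column count does not match training features")
    Xs = (X - model.feature_mean) / model.feature_sd
    preds = np.column_stack([est.predict(Xs) for est in model.estimators])
    return weighted_median(preds, model.estimator_weights)


def weighted_median(preds: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median with the cumulative-weight >= half-total rule."""
    preds = np.atleast_2d(np.asarray(preds, float))
    w = np.asarray(weights, float)
    order = np.argsort(preds, axis=1, kind="stable")
    sorted_preds = np.take_along_axis(preds, order, axis=1)
    cum = np.cumsum(w[order], axis=1)
    half = w.sum() / 2.0
    idx = np.argmax(cum >= half - 1e-15, axis=1)
    return sorted_preds[np.arange(preds.shape[0]), idx]
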