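"""Scikit-learn-style estimators for the click-task observer models.

Each estimator is a binary classifier over trials: ``X`` is the
(n_trials, n_clicks) matrix of signed click indicators (+1 left ear, -1
right ear, in stimulus order) and ``y`` the choices (1 = left, 0 = right).
``fit`` runs the multi-start maximum-likelihood machinery from
:mod:`clicknorm.fitting`; ``predict_proba`` returns the model's per-trial
choice probabilities.  The estimators compose with sklearn pipelines and
model selection (``get_params``/``set_params``/``clone`` work as usual).

>>> model = DivisiveNormalizationModel(n_starts=10, random_state=0)
>>> model.fit(X, y).params_          # doctest: +SKIP
DivNormParams(tau_R=..., tau_G=..., ...)
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from . import divnorm as dn
from . import accumulators as acc
from .task import TaskProtocol, dataset_from_arrays
from .fitting import fit_model
from .kernels import (
    DEFAULT_FLATNESS_FRACTION,
    classify_profile,
    fit_logistic_kernel,
)


class _ObserverEstimator(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing; subclasses set ``_model_tag``."""

    _model_tag: str = ""

    def __init__(
        self,
        protocol: TaskProtocol | None = None,
        n_starts: int = 50,
        bounds: dict | None = None,
        maxiter: int = 200,
        random_state: int | None = None,
    ):
        self.protocol = protocol
        self.n_starts = n_starts
        self.bounds = bounds
        self.maxiter = maxiter
        self.random_state = random_state

    def _effective_protocol(self) -> TaskProtocol:
        return self.protocol if self.protocol is not None else TaskProtocol()

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if not np.all(np.isin(y, (0, 1))):
            raise ValueError("y must contain only 0 (right) and 1 (left)")
        proto = self._effective_protocol()
        dataset = dataset_from_arrays(X.astype(int), y, proto)
        result = fit_model(
            self._model_tag,
            dataset,
            n_starts=self.n_starts,
            bounds=self.bounds,
            rng=np.random.default_rng(self.random_state),
            maxiter=self.maxiter,
        )
        self.result_ = result
        self.theta_ = result.theta_hat
        self.log_likelihood_ = result.log_likelihood
        self.aic_ = result.aic
        self.bic_ = result.bic
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def _p_left(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_proba(self, X):
        check_is_fitted(self, "theta_")
        X = check_array(X)
        p = np.clip(self._p_left(X), dn.PROB_CLIP, 1.0 - dn.PROB_CLIP)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y):
        """Mean per-trial Bernoulli log likelihood (higher is better)."""
        X, y = check_X_y(X, y)
        p = self.predict_proba(X)[:, 1]
        return float(np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


class DivisiveNormalizationModel(_ObserverEstimator):
    """Dynamic divisive-normalization observer (6 free parameters).

    Fitted attributes: ``params_`` (:class:`~clicknorm.divnorm.DivNormParams`),
    ``log_likelihood_``, ``aic_``, ``bic_``, ``kernel_``, ``kernel_shape_``.
    """

    _model_tag = "divnorm"

    def fit(self, X, y):
        super().fit(X, y)
        self.params_ = dn.DivNormParams(**self.theta_)
        proto = self._effective_protocol()
        kw = dn.kernel_weights(
            self.params_,
            _protocol_train(proto),
        )
        self.kernel_ = kw
        self.kernel_shape_ = classify_profile(
            kw.per_click_weight, DEFAULT_FLATNESS_FRACTION
        ).label
        return self

    def _p_left(self, X):
        proto = self._effective_protocol()
        return dn.choice_probability_matrix(
            self.params_, X, proto.click_times, proto.stimulus_duration
        )


class DriftDiffusionModel(_ObserverEstimator):
    """Basic DDM: flat integration, noise sigma_a, side bias (2 parameters)."""

    _model_tag = "ddm"

    def fit(self, X, y):
        super().fit(X, y)
        self.params_ = acc.LCAParams(
            lam=0.0, sigma_a=self.theta_["sigma_a"], bias=self.theta_["bias"]
        )
        return self

    def _p_left(self, X):
        proto = self._effective_protocol()
        return acc.lca_choice_probability_matrix(
            self.params_, X, proto.click_times, proto.stimulus_duration
        )


class LeakyAccumulatorModel(_ObserverEstimator):
    """LCA: memory drift lam plus noise and bias (3 parameters)."""

    _model_tag = "lca"

    def fit(self, X, y):
        super().fit(X, y)
        self.params_ = acc.LCAParams(**self.theta_)
        return self

    def _p_left(self, X):
        proto = self._effective_protocol()
        return acc.lca_choice_probability_matrix(
            self.params_, X, proto.click_times, proto.stimulus_duration
        )


class BoundedAccumulatorModel(_ObserverEstimator):
    """Brunton-style bounded adaptive accumulator (6 parameters).

    Fitting evaluates the density-propagation likelihood per trial, which is
    orders of magnitude slower than the closed-form models; intended for
    small n_starts / small datasets.
    """

    _model_tag = "brunton"

    def fit(self, X, y):
        super().fit(X, y)
        self.params_ = acc.BruntonParams(**self.theta_)
        return self

    def _p_left(self, X):
        proto = self._effective_protocol()
        T = proto.stimulus_duration
        out = np.empty(X.shape[0])
        for k, row in enumerate(X):
            train = _train_from_signs(row, proto)
            out[k] = acc.brunton_choice_probability(self.params_, train)
        return out


class IntegrationKernelRegression(BaseEstimator, ClassifierMixin):
    """Model-free integration kernel by penalized logistic regression.

    Fitted attributes: ``coef_`` (the 20 per-click weights), ``intercept_``
    (the side bias), ``se_`` (standard errors, bias last), ``shape_`` (the
    kernel phenotype under the default classifier).
    """

    def __init__(
        self,
        ridge: float = 0.0,
        flatness_fraction: float = DEFAULT_FLATNESS_FRACTION,
        protocol: TaskProtocol | None = None,
    ):
        self.ridge = ridge
        self.flatness_fraction = flatness_fraction
        self.protocol = protocol

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        proto = self.protocol if self.protocol is not None else TaskProtocol()
        dataset = dataset_from_arrays(X.astype(int), y, proto)
        est = fit_logistic_kernel(dataset, ridge=self.ridge)
        self.estimate_ = est
        self.coef_ = est.beta_click
        self.intercept_ = est.beta_bias
        self.se_ = est.standard_errors
        self.shape_ = classify_profile(est.beta_click, self.flatness_fraction).label
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        from scipy.special import expit

        p = expit(X @ self.coef_ + self.intercept_)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _protocol_train(proto: TaskProtocol):
    from .task import ClickTrain

    return ClickTrain(
        proto.click_times,
        np.ones(proto.n_clicks, dtype=int),
        proto.stimulus_duration,
    )


def _train_from_signs(signs: np.ndarray, proto: TaskProtocol):
    from .task import ClickTrain

    return ClickTrain(
        proto.click_times, np.asarray(signs, int), proto.stimulus_duration
    )
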