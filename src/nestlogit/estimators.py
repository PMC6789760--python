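"""Scikit-learn style estimators over the MML-EM engine.

Each estimator fits one IRT family with ``fit(X)`` and scores abilities
with ``transform(X)`` (a persons x 2 array of EAP estimate and posterior
SD). ``X`` may be the package's own containers (:class:`BinaryMatrix`,
:class:`ResponseMatrix`) or a plain integer array: 0/1 scores for the
binary families (-1 or NaN missing), 1-based category codes for the
nominal families (0 or NaN missing, key passed to ``fit``).

Fitted attributes follow sklearn conventions (trailing underscore):
``items_``, ``loglik_``, ``n_params_``, ``converged_``, ``n_cycles_``,
``result_`` (the full :class:`FitResult`). The estimators compose with
sklearn tooling via ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data import BinaryMatrix, ResponseMatrix, collapse_binary
from .em import EMConfig, FitResult, fit_em, marginal_loglik, standard_errors
from .models import QuadratureGrid
from .scoring import AbilityEstimates, eap_scores, empirical_reliability, reliability_function

__all__ = ["BinaryLogisticIRT", "NominalResponseIRT", "NestedLogitIRT"]


def _as_binary(X) -> BinaryMatrix:
    if isinstance(X, BinaryMatrix):
        return X
    if isinstance(X, ResponseMatrix):
        return collapse_binary(X)
    x = np.asarray(X, dtype=float)
    scores = np.where(np.isnan(x), -1, x).astype(int)
    return BinaryMatrix(scores)


def _as_nominal(X, key) -> ResponseMatrix:
    if isinstance(X, ResponseMatrix):
        return X
    if key is None:
        raise ValueError("nominal data passed as an array requires key=")
    x = np.asarray(X, dtype=float)
    codes = np.where(np.isnan(x), 0, x).astype(int)
    key = np.asarray(key, dtype=int)
    m = np.maximum(codes.max(axis=0), key)
    return ResponseMatrix(codes, key, np.maximum(m, 2))


class _BaseIRT(TransformerMixin, BaseEstimator):
    def __init__(self, n_quad=61, quad_bound=6.0, tol=1e-4, max_cycles=500):
        self.n_quad = n_quad
        self.quad_bound = quad_bound
        self.tol = tol
        self.max_cycles = max_cycles

    def _grid(self) -> QuadratureGrid:
        return QuadratureGrid.normal(self.n_quad, self.quad_bound)

    def _config(self) -> EMConfig:
        return EMConfig(tol=self.tol, max_cycles=self.max_cycles)

    def _coerce(self, X, key=None):
        raise NotImplementedError

    def _model_tag(self) -> str:
        raise NotImplementedError

    def fit(self, X, y=None, key=None):
        data = self._coerce(X, key)
        result = fit_em(data, self._model_tag(), grid=self._grid(), config=self._config())
        self.result_: FitResult = result
        self.items_ = result.items
        self.loglik_ = result.loglik
        self.n_params_ = result.n_params
        self.converged_ = result.converged
        self.n_cycles_ = result.n_cycles
        self.n_features_in_ = data.n_items
        self.se_ = None
        return self

    def eap(self, X, key=None) -> AbilityEstimates:
        check_is_fitted(self, "result_")
        return eap_scores(self.result_, self._coerce(X, key))

    def transform(self, X) -> np.ndarray:
        est = self.eap(X, key=getattr(self, "_fit_key_", None))
        return np.column_stack([est.theta, est.post_sd])

    def score(self, X, y=None) -> float:
        """Mean marginal log-likelihood per person."""
        check_is_fitted(self, "result_")
        data = self._coerce(X, getattr(self, "_fit_key_", None))
        return marginal_loglik(self.items_, data, self.result_.grid) / data.n_persons

    def compute_standard_errors(self, X, key=None):
        check_is_fitted(self, "result_")
        self.se_ = standard_errors(self.result_, self._coerce(X, key))
        self.result_.se = self.se_
        return self.se_

    def empirical_reliability(self, X, key=None) -> float:
        return empirical_reliability(self.eap(X, key))

    def reliability_curve(self, theta_grid=None):
        check_is_fitted(self, "result_")
        return reliability_function(self.result_, theta_grid)


class BinaryLogisticIRT(_BaseIRT):
    """Binary logistic IRT (1PL, 2PL, 3PL or 4PL) fit by MML-EM.

    Parameters
    ----------
    model : str
        Family tag, one of ``"1PL"``, ``"2PL"``, ``"3PL"``, ``"4PL"``.
    """

    def __init__(self, model="2PL", n_quad=61, quad_bound=6.0, tol=1e-4, max_cycles=500):
        super().__init__(n_quad=n_quad, quad_bound=quad_bound, tol=tol, max_cycles=max_cycles)
        self.model = model

    def _model_tag(self):
        return self.model.upper()

    def _coerce(self, X, key=None):
        return _as_binary(X)


class NominalResponseIRT(_BaseIRT):
    """Bock's Nominal Response Model fit by MML-EM."""

    def _model_tag(self):
        return "NRM"

    def _coerce(self, X, key=None):
        return _as_nominal(X, key)

    def fit(self, X, y=None, key=None):
        self._fit_key_ = None if isinstance(X, ResponseMatrix) else key
        return super().fit(X, y, key=key)


class NestedLogitIRT(_BaseIRT):
    """Suh-Bolt nested logit model (2PNL, 3PNL or 4PNL) fit by MML-EM.

    Level 1 is the matching binary family on correct vs. incorrect;
    level 2 is a softmax over the distractors given an incorrect response.
    """

    def __init__(self, model="3PNL", n_quad=61, quad_bound=6.0, tol=1e-4, max_cycles=500):
        super().__init__(n_quad=n_quad, quad_bound=quad_bound, tol=tol, max_cycles=max_cycles)
        self.model = model

    def _model_tag(self):
        return self.model.upper()

    def _coerce(self, X, key=None):
        return _as_nominal(X, key)

    def fit(self, X, y=None, key=None):
        self._fit_key_ = None if isinstance(X, ResponseMatrix) else key
        return super().fit(X, y, key=key)
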