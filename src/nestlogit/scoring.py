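"""EAP ability scoring and reliability.

Abilities are scored expected-a-posteriori (EAP) on the quadrature grid:
the posterior over nodes is proportional to the prior weight times the
response-pattern likelihood, and the score/posterior SD are its first two
moments. Conditional reliability derives from the test information under
the unit-variance prior, ``r(theta) = I(theta) / (I(theta) + 1)``; marginal
empirical reliability is the variance-ratio estimate
``Var(theta_hat) / (Var(theta_hat) + mean(post_sd^2))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .em import FitResult, _codes0, _log_tables, _person_loglik
from .models import QuadratureGrid, test_information

__all__ = [
    "AbilityEstimates",
    "ReliabilityReport",
    "eap_scores",
    "reliability_function",
    "empirical_reliability",
]


@dataclass
class AbilityEstimates:
    """EAP ability estimates with posterior SDs, one row per person."""

    theta: np.ndarray
    post_sd: np.ndarray
    model_tag: str = ""

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.post_sd = np.asarray(self.post_sd, dtype=float)
        if self.theta.shape != self.post_sd.shape or self.theta.ndim != 1:
            raise ValueError("theta and post_sd must be 1-d arrays of equal length")

    @property
    def n_persons(self) -> int:
        return self.theta.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person": np.arange(1, self.n_persons + 1),
                "theta_hat": self.theta,
                "post_sd": self.post_sd,
                "model_tag": self.model_tag,
            }
        )


@dataclass
class ReliabilityReport:
    """Marginal empirical reliability plus the conditional reliability curve."""

    empirical: float | None
    curve: pd.DataFrame  # columns: theta, information, reliability


def eap_scores(fit: FitResult, data, grid: QuadratureGrid | None = None) -> AbilityEstimates:
    """Expected-a-posteriori scores and posterior SDs for every person."""
    grid = grid or fit.grid
    codes0 = _codes0(data)
    if codes0.shape[1] != len(fit.items):
        raise ValueError("data item count does not match the fitted model")
    ll = _person_loglik(_log_tables(fit.items, grid), codes0, grid)
    post = np.exp(ll - logsumexp(ll, axis=1)[:, None])
    theta = post @ grid.nodes
    var = post @ grid.nodes**2 - theta**2
    sd = np.sqrt(np.clip(var, 1e-12, None))
    empty = (codes0 < 0).all(axis=1)
    theta[empty], sd[empty] = 0.0, 1.0
    return AbilityEstimates(theta=theta, post_sd=sd, model_tag=fit.model_tag)


def reliability_function(fit: FitResult, theta_grid=None) -> ReliabilityReport:
    """Conditional reliability r(theta) = I(theta) / (I(theta) + 1) on a grid."""
    theta_grid = fit.grid.nodes if theta_grid is None else np.asarray(theta_grid, float)
    info = test_information(fit.items, theta_grid)
    curve = pd.DataFrame(
        {"theta": theta_grid, "information": info, "reliability": info / (info + 1.0)}
    )
    return ReliabilityReport(empirical=None, curve=curve)


def empirical_reliability(est: AbilityEstimates) -> float:
    """Marginal empirical reliability: Var(theta_hat)/(Var(theta_hat)+mean(post_sd^2))."""
    if est.n_persons < 2:
        raise ValueError("empirical reliability needs at least 2 persons")
    v = float(np.var(est.theta, ddof=1))
    mse = float(np.mean(est.post_sd**2))
    if v + mse <= 0:
        raise ValueError("degenerate score set: zero total variance")
    return v / (v + mse)
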