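"""Bootstrap inference for the reliability gain between two scorings.

The gain is the difference in marginal empirical reliability between a
nested-logit scoring and its binary-collapse counterpart on the same
persons. Persons are resampled with replacement; both reliabilities are
recomputed on each resample's paired (theta_hat, post_sd) records, i.e. the
bootstrap is conditional on the fitted item parameters (models are not
refit per replicate). A Wald z uses the bootstrap SE; the CI is the
percentile interval on the same resamples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .scoring import AbilityEstimates, empirical_reliability

__all__ = ["GainTest", "reliability_gain"]


@dataclass
class GainTest:
    """Reliability gain (a minus b) with bootstrap CI, Wald z and p."""

    delta_r: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    n_boot: int
    seed: int

    def to_row(self, model_pair: str = "") -> dict:
        return {
            "model_pair": model_pair,
            "delta_r": self.delta_r,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "z": self.z,
            "p": self.p,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _rel(theta: np.ndarray, sd2: np.ndarray) -> float:
    v = np.var(theta, ddof=1)
    return v / (v + sd2.mean())


def reliability_gain(
    est_a: AbilityEstimates,
    est_b: AbilityEstimates,
    n_boot: int = 2000,
    seed: int = 0,
) -> GainTest:
    """Bootstrap test of the empirical-reliability difference (a minus b)."""
    if est_a.n_persons != est_b.n_persons:
        raise ValueError("ability estimates must cover the same persons in the same order")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = est_a.n_persons
    delta = empirical_reliability(est_a) - empirical_reliability(est_b)
    sd2_a, sd2_b = est_a.post_sd**2, est_b.post_sd**2
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boot[b] = _rel(est_a.theta[idx], sd2_a[idx]) - _rel(est_b.theta[idx], sd2_b[idx])
    se = float(np.std(boot, ddof=1))
    z = float(delta / se) if se > 0 else 0.0
    p = float(2.0 * norm.sf(abs(z))) if se > 0 else (1.0 if delta == 0 else 0.0)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return GainTest(
        delta_r=float(delta), ci_low=float(lo), ci_high=float(hi),
        z=z, p=p, n_boot=n_boot, seed=seed,
    )
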