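"""Item response kernels for multiple-choice ability tests.

Three model families are implemented:

* **Binary logistic** (1PL/2PL/3PL/4PL): the probability of a correct
  response is ``gamma + (delta - gamma) * logistic(beta + alpha * theta)``,
  in slope-intercept form.  ``gamma`` is the lower asymptote (correct
  guessing), ``delta`` the upper asymptote (slipping / inattention).
* **Nominal response** (Bock): each of the ``m`` response categories has a
  propensity ``exp(zeta_v + lambda_v * theta)``; category probabilities are
  the softmax of the propensities.
* **Nested logit** (Suh & Bolt): a two-level model.  Level 1 is a binary
  logistic model for correct vs. incorrect; level 2 distributes the
  incorrect probability mass over the distractors with a nominal
  (softmax) model, so ``P(v) = (1 - P(correct)) * softmax_v`` for each
  distractor ``v``.

All kernels are vectorised over ``theta``.  Identification of the nominal
blocks uses a baseline (reference) category with ``zeta = lambda = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_softmax
from scipy.stats import norm

__all__ = [
    "BinaryItemParams",
    "NominalItemParams",
    "NestedItemParams",
    "QuadratureGrid",
    "prob_binary",
    "prob_nominal",
    "prob_nested",
    "category_probs",
    "item_information",
    "test_information",
]

#: finite-difference step for numeric information of nominal/nested items
FD_STEP = 1e-5


@dataclass
class BinaryItemParams:
    """Slope-intercept parameters of a binary logistic item.

    ``gamma``/``delta`` live on the probability scale; constrained families
    simply fix them (2PL: gamma=0, delta=1; 3PL: delta=1).
    """

    alpha: float
    beta: float
    gamma: float = 0.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0 and 0.0 <= self.delta <= 1.0):
            raise ValueError(
                f"asymptotes must lie in [0, 1]; got gamma={self.gamma}, delta={self.delta}"
            )
        if self.gamma > self.delta:
            raise ValueError("lower asymptote gamma exceeds upper asymptote delta")


@dataclass
class NominalItemParams:
    """Category intercepts and slopes of a nominal (softmax) item.

    Exactly one reference category carries ``zeta = lambda = 0`` under the
    baseline identification convention (index ``ref``).
    """

    zeta: np.ndarray
    lam: np.ndarray
    ref: int = 0

    def __post_init__(self) -> None:
        self.zeta = np.asarray(self.zeta, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if self.zeta.shape != self.lam.shape or self.zeta.ndim != 1:
            raise ValueError("zeta and lam must be 1-d arrays of equal length")
        if self.n_categories < 2:
            raise ValueError("a nominal item needs at least 2 categories")
        if not (0 <= self.ref < self.n_categories):
            raise ValueError("reference category out of range")

    @property
    def n_categories(self) -> int:
        return self.zeta.size


@dataclass
class NestedItemParams:
    """Two-level nested logit item.

    ``level1`` governs correct vs. incorrect; ``zeta``/``lam`` are the
    distractor propensities, stored in category order over all ``m``
    categories with the entry at ``key`` unused (kept at 0).  ``ref`` is the
    baseline distractor (``zeta = lambda = 0``).
    """

    level1: BinaryItemParams
    zeta: np.ndarray
    lam: np.ndarray
    key: int
    ref: int = field(default=-1)

    def __post_init__(self) -> None:
        self.zeta = np.asarray(self.zeta, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        m = self.n_categories
        if self.zeta.shape != self.lam.shape or self.zeta.ndim != 1 or m < 2:
            raise ValueError("zeta and lam must be 1-d arrays of equal length >= 2")
        if self.ref < 0:
            # default baseline: the last category that is not the key
            self.ref = m - 1 if self.key != m - 1 else m - 2
        if not (0 <= self.key < m) or not (0 <= self.ref < m):
            raise ValueError("key/ref category out of range")
        if self.ref == self.key:
            raise ValueError("reference distractor cannot be the keyed category")

    @property
    def n_categories(self) -> int:
        return self.zeta.size

    @property
    def distractor_idx(self) -> np.ndarray:
        m = self.n_categories
        return np.array([v for v in range(m) if v != self.key])


@dataclass
class QuadratureGrid:
    """Latent-trait integration grid under the N(0, 1) prior.

    Equally spaced nodes with weights proportional to the standard normal
    density, normalised to sum to one.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("quadrature nodes must be strictly increasing")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be nonnegative and sum to 1")

    @classmethod
    def normal(cls, n_nodes: int = 61, bound: float = 6.0) -> "QuadratureGrid":
        nodes = np.linspace(-bound, bound, n_nodes)
        w = norm.pdf(nodes)
        return cls(nodes, w / w.sum())

    def __len__(self) -> int:
        return self.nodes.size


def prob_binary(params: BinaryItemParams, theta) -> np.ndarray:
    """Probability of a correct response under the 4P binary kernel."""
    theta = np.asarray(theta, dtype=float)
    s = expit(params.beta + params.alpha * theta)
    return params.gamma + (params.delta - params.gamma) * s


def _log_softmax_block(zeta: np.ndarray, lam: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Overflow-safe log category probabilities, shape (*theta.shape, m)."""
    logits = zeta + np.multiply.outer(theta, lam)
    return log_softmax(logits, axis=-1)


def prob_nominal(params: NominalItemParams, theta) -> np.ndarray:
    """Nominal-response category probabilities, shape (..., m)."""
    theta = np.asarray(theta, dtype=float)
    return np.exp(_log_softmax_block(params.zeta, params.lam, theta))


def prob_nested(params: NestedItemParams, theta) -> np.ndarray:
    """Nested-logit category probabilities over all m categories.

    The entry at ``key`` equals the level-1 correct probability; the
    distractor entries split the remaining mass with a softmax.
    """
    theta = np.asarray(theta, dtype=float)
    p1 = prob_binary(params.level1, theta)
    d = params.distractor_idx
    sm = np.exp(_log_softmax_block(params.zeta[d], params.lam[d], theta))
    out = np.empty(theta.shape + (params.n_categories,))
    out[..., params.key] = p1
    out[..., d] = (1.0 - p1)[..., None] * sm
    return out


def category_probs(item, theta) -> np.ndarray:
    """Category probabilities for any item type.

    Binary items are treated as two-category items ordered
    (incorrect, correct) so every family shares one likelihood interface.
    """
    if isinstance(item, BinaryItemParams):
        p = prob_binary(item, theta)
        return np.stack([1.0 - p, p], axis=-1)
    if isinstance(item, NominalItemParams):
        return prob_nominal(item, theta)
    if isinstance(item, NestedItemParams):
        return prob_nested(item, theta)
    raise TypeError(f"unsupported item parameter type: {type(item).__name__}")


def item_information(item, theta) -> np.ndarray:
    """Fisher information I(theta) = sum_v (dP_v/dtheta)^2 / P_v.

    Binary items use the analytic two-category form; nominal and nested
    items use central differences (step ``FD_STEP``).
    """
    theta = np.asarray(theta, dtype=float)
    if isinstance(item, BinaryItemParams):
        s = expit(item.beta + item.alpha * theta)
        dp = item.alpha * (item.delta - item.gamma) * s * (1.0 - s)
        p = item.gamma + (item.delta - item.gamma) * s
        denom = np.clip(p * (1.0 - p), 1e-300, None)
        return dp**2 / denom
    p = category_probs(item, theta)
    dp = (category_probs(item, theta + FD_STEP) - category_probs(item, theta - FD_STEP)) / (
        2.0 * FD_STEP
    )
    return (dp**2 / np.clip(p, 1e-300, None)).sum(axis=-1)


def test_information(items, theta) -> np.ndarray:
    """Test information: sum of item informations at theta."""
    theta = np.asarray(theta, dtype=float)
    return sum(item_information(it, theta) for it in items)
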