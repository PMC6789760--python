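import numpy as np
import pytest

from nestlogit import (
    BinaryItemParams,
    NestedItemParams,
    QuadratureGrid,
    collapse_binary,
    simulate,
)


@pytest.fixture(scope="session")
def grid() -> QuadratureGrid:
    return QuadratureGrid.normal()


@pytest.fixture(scope="session")
def small_binary_bank() -> list:
    """Six 2PL items spanning easy to hard."""
    betas = [1.5, 0.8, 0.3, -0.3, -0.8, -1.5]
    alphas = [1.2, 0.9, 1.5, 1.1, 0.7, 1.3]
    return [BinaryItemParams(a, b) for a, b in zip(alphas, betas)]


def make_nested_bank(
    n_items: int = 6,
    m: int = 4,
    distractor_slope_spread: float = 1.0,
    gamma: float = 0.0,
    seed: int = 1234,
) -> list:
    """Nested-logit bank with controllable distractor informativeness.

    ``distractor_slope_spread`` scales the distractor slopes; at 0 the
    distractors carry no ability information.
    """
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n_items):
        level1 = BinaryItemParams(
            alpha=float(rng.uniform(0.8, 1.8)),
            beta=float(rng.uniform(-1.5, 1.5)),
            gamma=gamma,
        )
        lam = np.zeros(m)
        zeta = np.zeros(m)
        lam[1:-1] = distractor_slope_spread * rng.uniform(-1.0, 1.0, m - 2)
        zeta[1:-1] = rng.uniform(-0.8, 0.8, m - 2)
        items.append(NestedItemParams(level1=level1, zeta=zeta, lam=lam, key=0, ref=m - 1))
    return items


@pytest.fixture(scope="session")
def small_nested_bank() -> list:
    return make_nested_bank()


@pytest.fixture(scope="session")
def small_binary_data(small_binary_bank):
    data, theta = simulate(small_binary_bank, 800, seed=42)
    return data, theta


@pytest.fixture(scope="session")
def small_nominal_data(small_nested_bank):
    data, theta = simulate(small_nested_bank, 800, seed=43)
    return data, theta


@pytest.fixture(scope="session")
def small_nominal_binary(small_nominal_data):
    data, _ = small_nominal_data
    return collapse_binary(data)
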