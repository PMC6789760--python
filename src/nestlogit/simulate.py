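"""Synthetic response generation and the published GF20 item banks.

The generator emulates the study design the analysis assumes: abilities
drawn from the standard normal, and responses drawn item by item from the
model-implied category distribution at each person's ability. Sampling
uses inverse-CDF with a single uniform draw per response; the draw order is
fixed (abilities first, then one uniform vector per item, left to right) so
a seed fully determines the output.

``paper_fixture`` returns the 20-item GF20 parameter banks transcribed from
the published fitted models (binary 2PL/3PL/4PL and nested 2PNL/3PNL/4PNL).
The test's answer key is not published, so the fixtures place the correct
option at category 1 and the four listed distractors at categories 2-5,
with the implicit baseline distractor (zeta = lambda = 0) at category 6;
reliability analyses are invariant to this labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .data import BinaryMatrix, ResponseMatrix, read_item_params
from .models import BinaryItemParams, NestedItemParams, category_probs

__all__ = ["SimulationSpec", "simulate_responses", "simulate", "paper_fixture", "FIXTURE_IDS"]

FIXTURE_IDS = (
    "binary_2pl",
    "binary_3pl",
    "binary_4pl",
    "nested_2pnl",
    "nested_3pnl",
    "nested_4pnl",
)


@dataclass
class SimulationSpec:
    """A reproducible simulation design: bank, sample size and seed."""

    n_persons: int
    item_bank: list
    seed: int
    theta: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not self.item_bank:
            raise ValueError("item bank is empty")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
            if self.theta.shape != (self.n_persons,):
                raise ValueError("explicit theta must have one entry per person")


def simulate_responses(spec: SimulationSpec):
    """Draw responses from the bank's category distributions.

    Returns ``(BinaryMatrix, theta)`` for binary banks and
    ``(ResponseMatrix, theta)`` for nominal/nested banks.
    """
    rng = np.random.default_rng(spec.seed)
    theta = rng.standard_normal(spec.n_persons) if spec.theta is None else spec.theta
    items = spec.item_bank
    n = spec.n_persons
    codes = np.empty((n, len(items)), dtype=int)
    for i, it in enumerate(items):
        probs = category_probs(it, theta)  # (n, m)
        u = rng.random(n)
        codes[:, i] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    if all(isinstance(it, BinaryItemParams) for it in items):
        return BinaryMatrix(codes), theta
    key = np.array(
        [it.key + 1 if isinstance(it, NestedItemParams) else 1 for it in items]
    )
    n_cat = np.array([it.n_categories for it in items])
    return ResponseMatrix(codes + 1, key, n_cat), theta


def simulate(item_bank, n_persons: int, seed: int, theta=None):
    """Convenience wrapper over :func:`simulate_responses`."""
    return simulate_responses(
        SimulationSpec(n_persons=n_persons, item_bank=list(item_bank), seed=seed, theta=theta)
    )


_FIXTURE_FILES = {
    "binary_2pl": ("gf20_2pl.csv", "2PL"),
    "binary_3pl": ("gf20_3pl.csv", "3PL"),
    "binary_4pl": ("gf20_4pl.csv", "4PL"),
    "nested_2pnl": ("gf20_2pnl.csv", "2PNL"),
    "nested_3pnl": ("gf20_3pnl.csv", "3PNL"),
    "nested_4pnl": ("gf20_4pnl.csv", "4PNL"),
}


def fixture_path(table_id: str):
    """Path to the packaged parameter table for a fixture id."""
    if table_id not in _FIXTURE_FILES:
        raise ValueError(f"unknown table_id {table_id!r}; choose one of {FIXTURE_IDS}")
    fname, _ = _FIXTURE_FILES[table_id]
    return resources.files("nestlogit.tables") / fname


def paper_fixture(table_id: str):
    """The published 20-item GF20 bank for one fitted model family."""
    if table_id not in _FIXTURE_FILES:
        raise ValueError(f"unknown table_id {table_id!r}; choose one of {FIXTURE_IDS}")
    fname, tag = _FIXTURE_FILES[table_id]
    with resources.as_file(resources.files("nestlogit.tables") / fname) as path:
        return read_item_params(path, tag)
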