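"""Data containers and delimited-text I/O for nominal multiple-choice responses.

Response codes are 1-based on disk and in the public containers (category
``1..m_i`` per item, ``0`` marks a missing response); internal estimation
code re-indexes to 0-based. The answer key gives, per item, the category
index of the correct option.

Item-parameter tables are comma-separated files with a header row; one
schema per model family (see ``PARAM_SCHEMAS``). Asymptotes may be stored
either on the probability scale (``gamma``/``delta`` columns) or the logit
scale (``logit_gamma``/``logit_delta``); logit-scale values are transformed
to probabilities on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .models import BinaryItemParams, NestedItemParams

__all__ = [
    "ResponseMatrix",
    "BinaryMatrix",
    "read_responses",
    "write_responses",
    "collapse_binary",
    "read_item_params",
    "PARAM_SCHEMAS",
]

MISSING = 0  #: missing-response sentinel in 1-based code matrices


@dataclass
class ResponseMatrix:
    """Persons x items nominal response codes plus the answer key.

    ``codes[j, i]`` is in ``1..n_categories[i]`` or ``MISSING``;
    ``key[i]`` is the 1-based correct category for item ``i``.
    """

    codes: np.ndarray
    key: np.ndarray
    n_categories: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        self.key = np.asarray(self.key, dtype=int)
        self.n_categories = np.asarray(self.n_categories, dtype=int)
        if self.codes.ndim != 2 or self.codes.shape[0] < 1 or self.codes.shape[1] < 1:
            raise ValueError("codes must be a nonempty 2-d matrix")
        n, i = self.codes.shape
        if self.key.shape != (i,) or self.n_categories.shape != (i,):
            raise ValueError("key and n_categories must have one entry per item")
        if np.any(self.n_categories < 2):
            raise ValueError("every item needs at least 2 categories")
        if np.any((self.key < 1) | (self.key > self.n_categories)):
            raise ValueError("answer key outside 1..m_i")
        bad = (self.codes != MISSING) & (
            (self.codes < 1) | (self.codes > self.n_categories[None, :])
        )
        if np.any(bad):
            j, i = np.argwhere(bad)[0]
            raise ValueError(
                f"response code {self.codes[j, i]} out of range 1..{self.n_categories[i]} "
                f"at person {j + 1}, item {i + 1}"
            )

    @property
    def n_persons(self) -> int:
        return self.codes.shape[0]

    @property
    def n_items(self) -> int:
        return self.codes.shape[1]


@dataclass
class BinaryMatrix:
    """Persons x items success/failure scores: 1 correct, 0 incorrect, -1 missing."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.ndim != 2 or self.scores.shape[0] < 1 or self.scores.shape[1] < 1:
            raise ValueError("scores must be a nonempty 2-d matrix")
        if not np.isin(self.scores, (-1, 0, 1)).all():
            raise ValueError("binary scores must be 0, 1 or -1 (missing)")

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]


def collapse_binary(responses: ResponseMatrix) -> BinaryMatrix:
    """Collapse distractors: 1 iff the code equals the key, missing stays missing."""
    scores = (responses.codes == responses.key[None, :]).astype(int)
    scores[responses.codes == MISSING] = -1
    return BinaryMatrix(scores)


def read_responses(path, key, n_categories=None) -> ResponseMatrix:
    """Read a delimited code table (header row, one column per item)."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as err:
        raise ValueError(f"malformed response table {path}: {err}") from None
    key = np.asarray(key, dtype=int)
    if df.shape[1] != key.size:
        raise ValueError(
            f"key length {key.size} does not match {df.shape[1]} response columns"
        )
    if n_categories is None:
        n_categories = np.full(key.size, max(2, int(df.to_numpy().max()), int(key.max())))
    return ResponseMatrix(df.to_numpy(dtype=int), key, n_categories)


def write_responses(responses: ResponseMatrix, path) -> None:
    cols = [f"item{i + 1}" for i in range(responses.n_items)]
    pd.DataFrame(responses.codes, columns=cols).to_csv(path, index=False)


# Required columns per model family. Either of the bracketed alternatives
# satisfies the asymptote requirement.
PARAM_SCHEMAS = {
    "1PL": ["beta"],
    "2PL": ["alpha", "beta"],
    "3PL": ["alpha", "beta", ("gamma", "logit_gamma")],
    "4PL": ["alpha", "beta", ("gamma", "logit_gamma"), ("delta", "logit_delta")],
}
_NESTED_OF = {"2PNL": "2PL", "3PNL": "3PL", "4PNL": "4PL"}


def _asymptote(row: pd.Series, name: str, default: float) -> float:
    if name in row.index and pd.notna(row[name]):
        value = float(row[name])
    elif f"logit_{name}" in row.index and pd.notna(row[f"logit_{name}"]):
        value = float(expit(row[f"logit_{name}"]))
    else:
        return default
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} outside [0, 1] after transform")
    return value


def _binary_from_row(row: pd.Series, model_tag: str) -> BinaryItemParams:
    gamma = _asymptote(row, "gamma", 0.0) if model_tag in ("3PL", "4PL") else 0.0
    delta = _asymptote(row, "delta", 1.0) if model_tag == "4PL" else 1.0
    alpha = float(row["alpha"]) if "alpha" in row.index else 1.0
    return BinaryItemParams(alpha=alpha, beta=float(row["beta"]), gamma=gamma, delta=delta)


def _check_schema(df: pd.DataFrame, model_tag: str) -> None:
    base = model_tag if model_tag in PARAM_SCHEMAS else _NESTED_OF[model_tag]
    for col in PARAM_SCHEMAS[base]:
        if isinstance(col, tuple):
            if not any(c in df.columns for c in col):
                raise ValueError(f"{model_tag} table needs one of columns {col}")
        elif col not in df.columns:
            raise ValueError(f"{model_tag} table is missing required column '{col}'")


def read_item_params(path, model_tag: str, key=None):
    """Read an item-parameter table for the given family.

    Binary families return ``list[BinaryItemParams]``. Nested families
    (``2PNL``/``3PNL``/``4PNL``) return ``list[NestedItemParams]``: the
    ``lam1..lamK``/``zeta1..zetaK`` columns are the listed distractors, a
    baseline distractor (``zeta = lambda = 0``) is appended after them, and
    the correct category is placed first unless ``key`` says otherwise.
    """
    df = pd.read_csv(path)
    model_tag = model_tag.upper()
    if model_tag in PARAM_SCHEMAS:
        _check_schema(df, model_tag)
        return [_binary_from_row(row, model_tag) for _, row in df.iterrows()]
    if model_tag not in _NESTED_OF:
        raise ValueError(f"unknown model_tag {model_tag!r}")
    _check_schema(df, model_tag)
    lam_cols = sorted(
        (c for c in df.columns if c.startswith("lam") and c[3:].isdigit()),
        key=lambda c: int(c[3:]),
    )
    zeta_cols = [f"zeta{c[3:]}" for c in lam_cols]
    if not lam_cols or any(c not in df.columns for c in zeta_cols):
        raise ValueError(f"{model_tag} table needs paired lamK/zetaK distractor columns")
    m = len(lam_cols) + 2  # listed distractors + baseline distractor + key
    n_items = len(df)
    key = np.ones(n_items, dtype=int) if key is None else np.asarray(key, dtype=int)
    items = []
    for (_, row), u in zip(df.iterrows(), key):
        level1 = _binary_from_row(row, _NESTED_OF[model_tag])
        zeta = np.zeros(m)
        lam = np.zeros(m)
        slots = [v for v in range(m) if v != u - 1]
        for slot, lc, zc in zip(slots, lam_cols, zeta_cols):
            lam[slot] = row[lc]
            zeta[slot] = row[zc]
        items.append(
            NestedItemParams(level1=level1, zeta=zeta, lam=lam, key=u - 1, ref=slots[-1])
        )
    return items
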