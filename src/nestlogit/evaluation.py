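"""Model comparison and absolute fit.

Relative fit: likelihood-ratio tests between nested families and the
small-sample corrected AIC. Absolute fit: a limited-information quadratic
form statistic (M2-type) built from first- and second-order response
margins, with CFI/TLI against an independence baseline, RMSEA and SRMR.

Margins. For binary families the margins are the full first- and
second-order success probabilities, ``s = I + I(I-1)/2``. For nominal and
nested families the univariate margins are all category proportions but
one per item, and each item pair contributes a single cross-moment of the
integer-scored categories — a reduced set that keeps the statistic
computable for heavily parametrised polytomous models. The statistic is
``M2 = N e' Dc (Dc' Xi Dc)^+ Dc' e`` where ``e`` is observed minus
model-implied margins, ``Xi`` the model-implied sampling covariance of the
margins, and ``Dc`` an orthogonal complement of the margin Jacobian; its
degrees of freedom are the margin count minus the number of parameters
identified by the margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space
from scipy.stats import chi2

from .data import BinaryMatrix, ResponseMatrix
from .em import FitResult, _codes0, bank_from_vector, bank_to_vector
from .models import NominalItemParams, QuadratureGrid, category_probs

__all__ = [
    "ComparisonRow",
    "GofReport",
    "lrt",
    "aicc",
    "limited_info_fit",
    "cronbach_alpha",
    "comparison_table",
]

# constrained -> set of families it is nested in
_NESTING = {
    "1PL": {"2PL", "3PL", "4PL"},
    "2PL": {"3PL", "4PL"},
    "3PL": {"4PL"},
    "2PNL": {"3PNL", "4PNL"},
    "3PNL": {"4PNL"},
}


@dataclass
class ComparisonRow:
    """One line of a model-comparison table."""

    model_tag: str
    loglik: float
    n_params: int
    aicc: float
    lrt_vs: str | None = None
    lrt_chisq: float | None = None
    lrt_df: int | None = None
    lrt_p: float | None = None


@dataclass
class GofReport:
    """Limited-information goodness-of-fit summary."""

    m2: float
    df: int
    p: float
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    n_margins: int


def lrt(fit_nested: FitResult, fit_full: FitResult) -> dict:
    """Likelihood-ratio test of a constrained family against a nesting one."""
    if fit_full.model_tag not in _NESTING.get(fit_nested.model_tag, set()):
        raise ValueError(
            f"{fit_nested.model_tag} is not nested in {fit_full.model_tag}; "
            "compare non-nested models by AICc instead"
        )
    if fit_nested.n_persons != fit_full.n_persons:
        raise ValueError("LRT requires both fits on the same data")
    chisq = 2.0 * (fit_full.loglik - fit_nested.loglik)
    df = fit_full.n_params - fit_nested.n_params
    return {
        "chisq": float(chisq),
        "df": int(df),
        "p": float(chi2.sf(max(chisq, 0.0), df)),
    }


def aicc(fit: FitResult) -> float:
    """Corrected AIC: -2 loglik + 2k + 2k(k+1)/(N-k-1)."""
    k, n = fit.n_params, fit.n_persons
    if n <= k + 1:
        raise ValueError(f"AICc undefined for N={n} <= k+1={k + 1}")
    return float(-2.0 * fit.loglik + 2 * k + 2.0 * k * (k + 1) / (n - k - 1))


def comparison_table(fits: list[FitResult]) -> list[ComparisonRow]:
    """AICc for every fit plus an LRT against the closest nesting neighbour."""
    rows = []
    by_tag = {f.model_tag: f for f in fits}
    for f in fits:
        try:
            crit = aicc(f)
        except ValueError:  # N <= k+1: criterion undefined for this sample
            crit = float("nan")
        row = ComparisonRow(f.model_tag, f.loglik, f.n_params, crit)
        parents = [t for t in _NESTING.get(f.model_tag, set()) if t in by_tag]
        if parents:
            parent = min(parents, key=lambda t: by_tag[t].n_params)
            res = lrt(f, by_tag[parent])
            row.lrt_vs = parent
            row.lrt_chisq, row.lrt_df, row.lrt_p = res["chisq"], res["df"], res["p"]
        rows.append(row)
    return rows


def cronbach_alpha(binary: BinaryMatrix) -> float:
    """Cronbach's alpha of the binary-scored test (complete rows)."""
    x = binary.scores
    if x.shape[1] < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    x = x[(x >= 0).all(axis=1)].astype(float)
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


# ---------------------------------------------------------------------------
# limited-information machinery
# ---------------------------------------------------------------------------
# a margin is a tuple of (item_index, weight_vector) factors; its value for
# a response pattern is the product over factors of weight[code]


def _margins_for(n_categories) -> list[tuple]:
    n_items = len(n_categories)
    margins = []
    if all(m == 2 for m in n_categories):
        one = np.array([0.0, 1.0])
        for i in range(n_items):
            margins.append(((i, one),))
        for i in range(n_items):
            for j in range(i + 1, n_items):
                margins.append(((i, one), (j, one)))
        return margins
    for i, m in enumerate(n_categories):
        for k in range(1, m):
            e = np.zeros(m)
            e[k] = 1.0
            margins.append(((i, e),))
    scores = [np.arange(m, dtype=float) for m in n_categories]
    for i in range(n_items):
        for j in range(i + 1, n_items):
            margins.append(((i, scores[i]), (j, scores[j])))
    return margins


def _observed_margins(codes0: np.ndarray, margins) -> np.ndarray:
    obs = np.empty(len(margins))
    for s, margin in enumerate(margins):
        mask = np.ones(codes0.shape[0], dtype=bool)
        val = np.ones(codes0.shape[0])
        for i, w in margin:
            c = codes0[:, i]
            mask &= c >= 0
            val *= w[np.clip(c, 0, None)]
        obs[s] = val[mask].mean()
    return obs


def _implied_margins(prob_tables, weights, margins) -> np.ndarray:
    mu = np.empty(len(margins))
    for s, margin in enumerate(margins):
        acc = np.ones(weights.size)
        for i, w in margin:
            acc *= prob_tables[i] @ w
        mu[s] = weights @ acc
    return mu


def _merge(margin_a, margin_b):
    factors = {}
    for i, w in margin_a + margin_b:
        factors[i] = factors[i] * w if i in factors else w
    return tuple(factors.items())


def _xi_matrix(prob_tables, weights, margins, mu) -> np.ndarray:
    s = len(margins)
    ezz = np.empty((s, s))
    for a in range(s):
        for b in range(a, s):
            acc = np.ones(weights.size)
            for i, w in _merge(margins[a], margins[b]):
                acc *= prob_tables[i] @ w
            ezz[a, b] = ezz[b, a] = weights @ acc
    return ezz - np.outer(mu, mu)


def _prob_tables(items, grid):
    return [category_probs(it, grid.nodes) for it in items]


def _jacobian(mu_fn, vec0: np.ndarray, h: float = 1e-5) -> np.ndarray:
    cols = []
    for j in range(vec0.size):
        vp, vm = vec0.copy(), vec0.copy()
        vp[j] += h
        vm[j] -= h
        cols.append((mu_fn(vp) - mu_fn(vm)) / (2 * h))
    return np.column_stack(cols)


def _quadratic_form(e, xi, jac, n_persons):
    dc = null_space(jac.T)
    if dc.shape[1] == 0:
        return 0.0, 0
    a = dc.T @ xi @ dc
    t = dc.T @ e
    stat = float(n_persons * t @ np.linalg.pinv(a, hermitian=True) @ t)
    return stat, dc.shape[1]


def _pair_correlations(prob_tables, weights, n_categories):
    """Model-implied Pearson correlations of integer-scored items."""
    scores = [np.arange(m, dtype=float) for m in n_categories]
    e1 = np.array([weights @ (pt @ s) for pt, s in zip(prob_tables, scores)])
    e2 = np.array([weights @ (pt @ s**2) for pt, s in zip(prob_tables, scores)])
    sd = np.sqrt(np.clip(e2 - e1**2, 1e-12, None))
    n_items = len(prob_tables)
    corr = np.zeros((n_items, n_items))
    for i in range(n_items):
        for j in range(i + 1, n_items):
            eij = weights @ ((prob_tables[i] @ scores[i]) * (prob_tables[j] @ scores[j]))
            corr[i, j] = (eij - e1[i] * e1[j]) / (sd[i] * sd[j])
    return corr


def _observed_correlations(codes0: np.ndarray) -> np.ndarray:
    n_items = codes0.shape[1]
    corr = np.zeros((n_items, n_items))
    for i in range(n_items):
        for j in range(i + 1, n_items):
            xi, xj = codes0[:, i], codes0[:, j]
            mask = (xi >= 0) & (xj >= 0)
            corr[i, j] = np.corrcoef(xi[mask], xj[mask])[0, 1]
    return corr


def _srmr(fit_tables, codes0, weights, n_categories) -> float:
    imp = _pair_correlations(fit_tables, weights, n_categories)
    obs = _observed_correlations(codes0)
    iu = np.triu_indices(codes0.shape[1], k=1)
    return float(np.sqrt(np.mean((obs[iu] - imp[iu]) ** 2)))


def _baseline_items(codes0, n_categories):
    """Independence model: free univariate category margins, zero slopes."""
    items = []
    for i, m in enumerate(n_categories):
        c = codes0[:, i]
        cnt = np.bincount(c[c >= 0], minlength=m) + 0.5
        zeta = np.log(cnt / cnt[0])
        zeta[0] = 0.0
        items.append(NominalItemParams(zeta=zeta, lam=np.zeros(m), ref=0))
    return items


def _baseline_mu_fn(items, grid, margins):
    def mu_fn(vec):
        pos = 0
        tables = []
        for it in items:
            m = it.n_categories
            zeta = np.zeros(m)
            zeta[1:] = vec[pos : pos + m - 1]
            pos += m - 1
            tables.append(category_probs(NominalItemParams(zeta, np.zeros(m)), grid.nodes))
        return _implied_margins(tables, grid.weights, margins)

    return mu_fn


def limited_info_fit(fit: FitResult, data, grid: QuadratureGrid | None = None) -> GofReport:
    """M2-type absolute fit with CFI/TLI/RMSEA/SRMR."""
    grid = grid or fit.grid
    codes0 = _codes0(data)
    n_persons = codes0.shape[0]
    if isinstance(data, ResponseMatrix):
        n_categories = list(data.n_categories)
    else:
        n_categories = [2] * data.n_items
    margins = _margins_for(n_categories)
    tables = _prob_tables(fit.items, grid)
    obs = _observed_margins(codes0, margins)
    mu = _implied_margins(tables, grid.weights, margins)
    e = obs - mu
    xi = _xi_matrix(tables, grid.weights, margins, mu)

    vec0 = bank_to_vector(fit.items, fit.model_tag)

    def mu_fn(vec):
        items = bank_from_vector(fit.items, fit.model_tag, vec)
        return _implied_margins(_prob_tables(items, grid), grid.weights, margins)

    m2, df = _quadratic_form(e, xi, _jacobian(mu_fn, vec0), n_persons)
    p = float(chi2.sf(m2, df)) if df > 0 else 1.0

    # independence baseline on the same margins
    base_items = _baseline_items(codes0, n_categories)
    base_tables = _prob_tables(base_items, grid)
    base_mu = _implied_margins(base_tables, grid.weights, margins)
    base_xi = _xi_matrix(base_tables, grid.weights, margins, base_mu)
    base_vec = np.concatenate([it.zeta[1:] for it in base_items])
    base_jac = _jacobian(_baseline_mu_fn(base_items, grid, margins), base_vec)
    m2_base, df_base = _quadratic_form(obs - base_mu, base_xi, base_jac, n_persons)

    num = max(m2 - df, 0.0)
    den = max(m2_base - df_base, num, np.finfo(float).tiny)
    cfi = min(1.0, 1.0 - num / den)
    if df_base > 0 and df > 0 and m2_base / df_base > 1.0:
        tli = (m2_base / df_base - m2 / df) / (m2_base / df_base - 1.0)
    else:
        tli = 1.0
    tli = min(1.0, tli)
    rmsea = float(np.sqrt(max(0.0, (m2 - df) / (df * n_persons)))) if df > 0 else 0.0
    srmr = _srmr(tables, codes0, grid.weights, n_categories)
    return GofReport(
        m2=m2, df=df, p=p, cfi=float(cfi), tli=float(tli),
        rmsea=rmsea, srmr=srmr, n_margins=len(margins),
    )
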