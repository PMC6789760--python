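"""Marginal maximum likelihood estimation by EM over a quadrature grid.

The observed-data likelihood integrates the latent ability out under the
N(0, 1) prior: ``L_j = sum_q w_q prod_i P(x_ij | theta_q)``. The E-step
computes posterior node weights per person and expected category counts per
item; the M-step maximises the expected complete-data log-likelihood item
by item (quasi-Newton, analytic gradients). For nested logit items the
expected complete-data log-likelihood separates exactly into a binary
level-1 part and a distractor softmax part, which are maximised
independently.

Asymptotes are optimised on the logit scale. Parameter standard errors use
the cross-product (outer product of gradients) approximation to the
information matrix; when that matrix cannot be Cholesky-factorised the SEs
are reported as unavailable with a diagnostic rather than fabricated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp, softmax

from .data import BinaryMatrix, ResponseMatrix
from .models import (
    BinaryItemParams,
    NestedItemParams,
    NominalItemParams,
    QuadratureGrid,
    category_probs,
)

__all__ = [
    "EMConfig",
    "FitResult",
    "SEResult",
    "fit_em",
    "marginal_loglik",
    "standard_errors",
    "N_ASYMPTOTE_FAMILIES",
]

BINARY_TAGS = ("1PL", "2PL", "3PL", "4PL")
NOMINAL_TAGS = ("NRM", "2PNL", "3PNL", "4PNL")
#: number of free level-1 parameters per binary family
_N_LEVEL1 = {"1PL": 1, "2PL": 2, "3PL": 3, "4PL": 4}
N_ASYMPTOTE_FAMILIES = ("3PL", "4PL", "3PNL", "4PNL")

_PFLOOR = 1e-300
_PCLIP = 1e-12
_LOGIT_BOUND = 12.0
_SLOPE_BOUND = 50.0


@dataclass
class EMConfig:
    """Estimation settings: convergence tolerance on the maximum absolute
    parameter change, EM cycle cap, and the M-step iteration cap."""

    tol: float = 1e-4
    max_cycles: int = 500
    mstep_maxiter: int = 100


@dataclass
class SEResult:
    """Per-parameter standard errors, or an explicit unavailable marker."""

    available: bool
    values: np.ndarray | None = None
    labels: list[str] | None = None
    reason: str | None = None


@dataclass
class FitResult:
    """Converged MML-EM fit of one model family."""

    model_tag: str
    items: list
    loglik: float
    n_params: int
    n_persons: int
    converged: bool
    n_cycles: int
    loglik_path: np.ndarray
    grid: QuadratureGrid
    key: np.ndarray | None = None
    se: SEResult | None = None
    stop_rule: str = ""


# ---------------------------------------------------------------------------
# parameter vectorisation (shared by the M-step, OPG standard errors and the
# limited-information Jacobian)
# ---------------------------------------------------------------------------

def _lgt(p: float) -> float:
    return float(logit(np.clip(p, expit(-_LOGIT_BOUND), expit(_LOGIT_BOUND))))


def _binary_vec(it: BinaryItemParams, family: str) -> list[float]:
    v = [it.alpha, it.beta]
    if family in ("3PL", "4PL"):
        v.append(_lgt(it.gamma))
    if family == "4PL":
        v.append(_lgt(it.delta))
    return v


def _binary_from_vec(v, family: str) -> BinaryItemParams:
    gamma = expit(v[2]) if family in ("3PL", "4PL") else 0.0
    delta = expit(v[3]) if family == "4PL" else 1.0
    return BinaryItemParams(alpha=v[0], beta=v[1], gamma=min(gamma, delta), delta=delta)


def _free_block_idx(it) -> np.ndarray:
    """Indices of categories with free softmax parameters."""
    if isinstance(it, NominalItemParams):
        return np.array([k for k in range(it.n_categories) if k != it.ref])
    return np.array([k for k in range(it.n_categories) if k not in (it.ref, it.key)])


def item_to_vector(it, family: str) -> np.ndarray:
    if isinstance(it, BinaryItemParams):
        v = _binary_vec(it, family)
        return np.array(v[1:] if family == "1PL" else v)
    if isinstance(it, NominalItemParams):
        free = _free_block_idx(it)
        return np.concatenate([it.zeta[free], it.lam[free]])
    free = _free_block_idx(it)
    lvl = family.replace("PNL", "PL")
    return np.concatenate([_binary_vec(it.level1, lvl), it.zeta[free], it.lam[free]])


def item_from_vector(it, family: str, v: np.ndarray):
    if isinstance(it, BinaryItemParams):
        if family == "1PL":
            return replace(it, beta=float(v[0]))
        return _binary_from_vec(v, family)
    if isinstance(it, NominalItemParams):
        free = _free_block_idx(it)
        zeta, lam = it.zeta.copy(), it.lam.copy()
        zeta[free], lam[free] = v[: free.size], v[free.size :]
        return replace(it, zeta=zeta, lam=lam)
    free = _free_block_idx(it)
    lvl = family.replace("PNL", "PL")
    k = _N_LEVEL1[lvl]
    level1 = _binary_from_vec(v[:k], lvl)
    zeta, lam = it.zeta.copy(), it.lam.copy()
    zeta[free], lam[free] = v[k : k + free.size], v[k + free.size :]
    return replace(it, level1=level1, zeta=zeta, lam=lam)


def bank_to_vector(items, family: str) -> np.ndarray:
    head = [np.array([items[0].alpha])] if family == "1PL" else []
    return np.concatenate(head + [item_to_vector(it, family) for it in items])


def bank_from_vector(items, family: str, v: np.ndarray):
    out = []
    pos = 0
    alpha = None
    if family == "1PL":
        alpha, pos = float(v[0]), 1
    for it in items:
        p = item_to_vector(it, family).size
        new = item_from_vector(it, family, v[pos : pos + p])
        if family == "1PL":
            new = replace(new, alpha=alpha)
        out.append(new)
        pos += p
    return out


def param_labels(items, family: str) -> list[str]:
    labels = ["alpha"] if family == "1PL" else []
    for i, it in enumerate(items, start=1):
        if isinstance(it, BinaryItemParams):
            names = ["beta"] if family == "1PL" else ["alpha", "beta"]
            if family in ("3PL", "4PL"):
                names.append("logit_gamma")
            if family == "4PL":
                names.append("logit_delta")
        else:
            free = _free_block_idx(it)
            names = []
            if isinstance(it, NestedItemParams):
                lvl = family.replace("PNL", "PL")
                names += ["alpha", "beta"]
                if lvl in ("3PL", "4PL"):
                    names.append("logit_gamma")
                if lvl == "4PL":
                    names.append("logit_delta")
            names += [f"zeta{k + 1}" for k in free] + [f"lam{k + 1}" for k in free]
        labels += [f"item{i}.{n}" for n in names]
    return labels


def n_free_params(items, family: str) -> int:
    return bank_to_vector(items, family).size


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _codes0(data) -> np.ndarray:
    """0-based category codes with -1 for missing."""
    if isinstance(data, ResponseMatrix):
        return data.codes - 1
    if isinstance(data, BinaryMatrix):
        return data.scores.copy()
    raise TypeError("data must be a ResponseMatrix or BinaryMatrix")


def _log_tables(items, grid: QuadratureGrid) -> list[np.ndarray]:
    tables = []
    floored = False
    for it in items:
        P = category_probs(it, grid.nodes)
        floored |= bool((P < _PFLOOR).any())
        tables.append(np.log(np.clip(P, _PFLOOR, None)))
    if floored:
        warnings.warn("category probabilities floored at 1e-300 in likelihood")
    return tables


def _person_loglik(log_tables, codes0, grid) -> np.ndarray:
    """(N, Q) joint log-likelihood including the prior weights."""
    n = codes0.shape[0]
    ll = np.tile(np.log(grid.weights), (n, 1))
    for i, logP in enumerate(log_tables):
        c = codes0[:, i]
        obs = c >= 0
        ll[obs] += logP[:, c[obs]].T
    return ll


def marginal_loglik(items, data, grid: QuadratureGrid) -> float:
    """Observed-data marginal log-likelihood; missing entries contribute no factor."""
    ll = _person_loglik(_log_tables(items, grid), _codes0(data), grid)
    return float(logsumexp(ll, axis=1).sum())


def _estep(items, codes0, grid):
    log_tables = _log_tables(items, grid)
    ll = _person_loglik(log_tables, codes0, grid)
    lse = logsumexp(ll, axis=1)
    post = np.exp(ll - lse[:, None])
    counts = []
    for i, logP in enumerate(log_tables):
        m = logP.shape[1]
        c = codes0[:, i]
        r = np.zeros((len(grid), m))
        for k in range(m):
            sel = c == k
            if sel.any():
                r[:, k] = post[sel].sum(axis=0)
        counts.append(r)
    return float(lse.sum()), post, counts


# ---------------------------------------------------------------------------
# M-step objectives (negative expected complete-data log-likelihood)
# ---------------------------------------------------------------------------

def _nll_binary(v, family, theta, r0, r1):
    """4P binary objective with analytic gradient on (alpha, beta[, lg, ld])."""
    alpha, beta = v[0], v[1]
    gamma = expit(v[2]) if family in ("3PL", "4PL") else 0.0
    delta = expit(v[3]) if family == "4PL" else 1.0
    s = expit(beta + alpha * theta)
    p = np.clip(gamma + (delta - gamma) * s, _PCLIP, 1 - _PCLIP)
    f = -(r1 @ np.log(p) + r0 @ np.log1p(-p))
    w = r1 / p - r0 / (1.0 - p)  # dF/dP with F the positive loglik
    ds = (delta - gamma) * s * (1.0 - s)
    g = [-(w * ds * theta).sum(), -(w * ds).sum()]
    if family in ("3PL", "4PL"):
        g.append(-(w * (1.0 - s) * gamma * (1.0 - gamma)).sum())
    if family == "4PL":
        g.append(-(w * s * delta * (1.0 - delta)).sum())
    return f, np.array(g)


def _nll_softmax(v, theta, r, free, n_cat):
    """Softmax block objective; v = zetas then lams over `free` categories."""
    zeta = np.zeros(n_cat)
    lam = np.zeros(n_cat)
    zeta[free], lam[free] = v[: free.size], v[free.size :]
    logits = zeta + np.multiply.outer(theta, lam)
    p = softmax(logits, axis=1)
    logp = logits - logsumexp(logits, axis=1)[:, None]
    f = -(r * logp).sum()
    resid = r - r.sum(axis=1)[:, None] * p  # (Q, m)
    g = -np.concatenate([resid[:, free].sum(axis=0), theta @ resid[:, free]])
    return f, g


def _mstep_item(it, family, theta, r, maxiter):
    opts = {"maxiter": maxiter}
    if isinstance(it, BinaryItemParams):
        v0 = np.array(_binary_vec(it, family))
        bounds = [(-_SLOPE_BOUND, _SLOPE_BOUND)] * 2 + [(-_LOGIT_BOUND, _LOGIT_BOUND)] * (
            v0.size - 2
        )
        res = minimize(
            _nll_binary, v0, args=(family, theta, r[:, 0], r[:, 1]),
            jac=True, method="L-BFGS-B", bounds=bounds, options=opts,
        )
        return _binary_from_vec(res.x, family)
    if isinstance(it, NominalItemParams):
        free = _free_block_idx(it)
        v0 = np.concatenate([it.zeta[free], it.lam[free]])
        res = minimize(
            _nll_softmax, v0, args=(theta, r, free, it.n_categories),
            jac=True, method="L-BFGS-B",
            bounds=[(-30, 30)] * v0.size, options=opts,
        )
        zeta, lam = it.zeta.copy(), it.lam.copy()
        zeta[free], lam[free] = res.x[: free.size], res.x[free.size :]
        return replace(it, zeta=zeta, lam=lam)
    # nested: the expected complete-data loglik separates into the binary
    # collapse (level 1) and the distractor softmax (level 2)
    lvl = family.replace("PNL", "PL")
    d = it.distractor_idx
    r_bin = np.column_stack([r[:, d].sum(axis=1), r[:, it.key]])
    level1 = _mstep_item(it.level1, lvl, theta, r_bin, maxiter)
    free = _free_block_idx(it)
    rd = r[:, d]
    free_within = np.searchsorted(d, free)
    v0 = np.concatenate([it.zeta[free], it.lam[free]])
    res = minimize(
        _nll_softmax, v0, args=(theta, rd, free_within, d.size),
        jac=True, method="L-BFGS-B", bounds=[(-30, 30)] * v0.size, options=opts,
    )
    zeta, lam = it.zeta.copy(), it.lam.copy()
    zeta[free], lam[free] = res.x[: free.size], res.x[free.size :]
    return replace(it, level1=level1, zeta=zeta, lam=lam)


def _mstep_1pl(items, theta, counts, maxiter):
    """Joint update of the common slope and per-item intercepts."""
    betas = np.array([it.beta for it in items])
    v0 = np.concatenate([[items[0].alpha], betas])
    r0 = np.stack([r[:, 0] for r in counts])
    r1 = np.stack([r[:, 1] for r in counts])

    def nll(v):
        alpha, beta = v[0], v[1:]
        s = expit(beta[:, None] + alpha * theta[None, :])
        p = np.clip(s, _PCLIP, 1 - _PCLIP)
        f = -(r1 * np.log(p) + r0 * np.log1p(-p)).sum()
        w = r1 / p - r0 / (1.0 - p)
        ds = s * (1.0 - s)
        g = np.concatenate([[-(w * ds * theta[None, :]).sum()], -(w * ds).sum(axis=1)])
        return f, g

    res = minimize(nll, v0, jac=True, method="L-BFGS-B", options={"maxiter": maxiter})
    alpha = float(res.x[0])
    return [replace(it, alpha=alpha, beta=float(b)) for it, b in zip(items, res.x[1:])]


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _start_values(codes0, model_tag, key0, n_categories):
    n, n_items = codes0.shape
    items = []
    for i in range(n_items):
        c = codes0[:, i]
        obs = c[c >= 0]
        if model_tag in BINARY_TAGS:
            p = obs.mean() if obs.size else 0.5
            if p in (0.0, 1.0):
                warnings.warn(
                    f"item {i + 1} is degenerate (all {'correct' if p else 'incorrect'}); "
                    "intercept capped at +/-10"
                )
                beta = 10.0 if p else -10.0
            else:
                beta = float(logit(p))
            gamma = expit(-1.386) if model_tag in ("3PL", "4PL") else 0.0
            delta = expit(2.197) if model_tag == "4PL" else 1.0
            items.append(BinaryItemParams(alpha=1.0, beta=beta, gamma=gamma, delta=delta))
            continue
        m = n_categories[i]
        cnt = np.bincount(obs, minlength=m) + 0.5
        if model_tag == "NRM":
            zeta = np.log(cnt / cnt[0])
            zeta[0] = 0.0
            # graded nonzero slope starts: an all-zero slope start is a
            # stationary point of EM (flat likelihood -> posterior = prior)
            lam = 0.25 * np.arange(m, dtype=float)
            items.append(NominalItemParams(zeta=zeta, lam=lam, ref=0))
        else:
            u = key0[i]
            p = (obs == u).mean() if obs.size else 0.5
            if p in (0.0, 1.0):
                warnings.warn(f"item {i + 1} is degenerate; intercept capped at +/-10")
                beta = 10.0 if p else -10.0
            else:
                beta = float(logit(p))
            lvl = model_tag.replace("PNL", "PL")
            level1 = BinaryItemParams(
                alpha=1.0,
                beta=beta,
                gamma=expit(-1.386) if lvl in ("3PL", "4PL") else 0.0,
                delta=expit(2.197) if lvl == "4PL" else 1.0,
            )
            d = [v for v in range(m) if v != u]
            ref = d[-1]
            zeta = np.zeros(m)
            zeta[d] = np.log(cnt[d] / cnt[ref])
            zeta[ref] = 0.0
            items.append(
                NestedItemParams(level1=level1, zeta=zeta, lam=np.zeros(m), key=u, ref=ref)
            )
    return items


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def fit_em(
    data,
    model_tag: str,
    grid: QuadratureGrid | None = None,
    config: EMConfig | None = None,
    start_items=None,
) -> FitResult:
    """Fit one model family by MML-EM.

    Binary families require a :class:`BinaryMatrix`; nominal families
    (NRM, 2PNL, 3PNL, 4PNL) require a :class:`ResponseMatrix` with its key.
    """
    model_tag = model_tag.upper()
    grid = grid or QuadratureGrid.normal()
    config = config or EMConfig()
    if model_tag in BINARY_TAGS:
        if not isinstance(data, BinaryMatrix):
            raise TypeError(f"{model_tag} requires binary success/failure data")
        key0, n_cat = None, np.full(data.n_items, 2)
    elif model_tag in NOMINAL_TAGS:
        if not isinstance(data, ResponseMatrix):
            raise TypeError(f"{model_tag} requires nominal response data with a key")
        key0, n_cat = data.key - 1, data.n_categories
    else:
        raise ValueError(f"unknown model_tag {model_tag!r}")

    codes0 = _codes0(data)
    items = start_items or _start_values(codes0, model_tag, key0, n_cat)
    theta = grid.nodes
    path = []
    converged = False
    stop_rule = "cycle cap reached"
    cycle = 0
    for cycle in range(1, config.max_cycles + 1):
        loglik, _, counts = _estep(items, codes0, grid)
        path.append(loglik)
        old = bank_to_vector(items, model_tag)
        if model_tag == "1PL":
            items = _mstep_1pl(items, theta, counts, config.mstep_maxiter)
        else:
            items = [
                _mstep_item(it, model_tag, theta, r, config.mstep_maxiter)
                for it, r in zip(items, counts)
            ]
        delta = np.max(np.abs(bank_to_vector(items, model_tag) - old))
        if delta < config.tol:
            converged = True
            stop_rule = f"max parameter change {delta:.2e} < tol {config.tol:g}"
            break
    loglik = marginal_loglik(items, data, grid)
    path.append(loglik)
    if not np.isfinite(loglik):
        raise RuntimeError("non-finite marginal log-likelihood at convergence")
    return FitResult(
        model_tag=model_tag,
        items=items,
        loglik=loglik,
        n_params=n_free_params(items, model_tag),
        n_persons=data.n_persons,
        converged=converged,
        n_cycles=cycle,
        loglik_path=np.array(path),
        grid=grid,
        key=None if key0 is None else key0 + 1,
        stop_rule=stop_rule,
    )


# ---------------------------------------------------------------------------
# standard errors (outer product of gradients)
# ---------------------------------------------------------------------------

def _dlog_tables(it, family, grid, h=1e-5):
    """(Q, m, p) numeric derivatives of log category probabilities."""
    v0 = item_to_vector(it, family)
    base_shape = category_probs(it, grid.nodes).shape
    D = np.empty(base_shape + (v0.size,))
    for j in range(v0.size):
        vp, vm = v0.copy(), v0.copy()
        vp[j] += h
        vm[j] -= h
        lp = np.log(np.clip(category_probs(item_from_vector(it, family, vp), grid.nodes), _PFLOOR, None))
        lm = np.log(np.clip(category_probs(item_from_vector(it, family, vm), grid.nodes), _PFLOOR, None))
        D[..., j] = (lp - lm) / (2 * h)
    return D


def _score_matrix(fit: FitResult, data, grid: QuadratureGrid) -> np.ndarray:
    codes0 = _codes0(data)
    _, post, _ = _estep(fit.items, codes0, grid)
    n = codes0.shape[0]
    family = fit.model_tag
    p_total = n_free_params(fit.items, family)
    S = np.zeros((n, p_total))
    pos = 1 if family == "1PL" else 0
    for i, it in enumerate(fit.items):
        D = _dlog_tables(it, family, grid)
        p_i = D.shape[-1]
        c = codes0[:, i]
        if family == "1PL":
            cols = np.array([0, 1 + i])  # shared slope, item intercept
            Du = _dlog_tables(replace(it), "2PL", grid)  # (Q, 2, 2): d/dalpha, d/dbeta
            for k in range(2):
                sel = c == k
                if sel.any():
                    S[np.ix_(sel, cols)] += post[sel] @ Du[:, k, :]
            continue
        cols = slice(pos, pos + p_i)
        for k in range(D.shape[1]):
            sel = c == k
            if sel.any():
                S[sel, cols] += post[sel] @ D[:, k, :]
        pos += p_i
    return S


def standard_errors(fit: FitResult, data, grid: QuadratureGrid | None = None) -> SEResult:
    """OPG standard errors; unavailable-marker when the matrix is not PD."""
    grid = grid or fit.grid
    labels = param_labels(fit.items, fit.model_tag)
    S = _score_matrix(fit, data, grid)
    info = S.T @ S
    try:
        L = np.linalg.cholesky(info)
        inv = np.linalg.inv(L)
        cov_diag = (inv**2).sum(axis=0)
    except np.linalg.LinAlgError:
        return SEResult(
            available=False,
            labels=labels,
            reason="cross-product information matrix is not positive definite "
            "(could not be inverted); estimates may be unstable",
        )
    if not np.all(np.isfinite(cov_diag)) or np.any(cov_diag <= 0):
        return SEResult(
            available=False, labels=labels,
            reason="non-finite or nonpositive variance from information inverse",
        )
    return SEResult(available=True, values=np.sqrt(cov_diag), labels=labels)
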