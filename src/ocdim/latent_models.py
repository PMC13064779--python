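"""Marginal maximum-likelihood fitting of latent symptom-structure models.

Three confirmatory structures for binary (or ordinal) item data:

* ``unidimensional`` — every item loads on a single latent trait (2PL);
* ``correlated_factors`` — each item loads on its domain factor only, with
  freely correlated factors;
* ``bifactor`` — every item loads on one general factor and on exactly one
  orthogonal domain-specific factor (the hierarchical model).

Estimation is deterministic Bock-Aitkin EM over fixed quadrature grids
(equally spaced normal-weighted nodes for the one-dimensional and bifactor
integrals; Gauss-Hermite tensor nodes for the correlated model): the
bifactor likelihood factorizes into per-domain two-dimensional integrals
given the general factor, and the correlated model integrates over a full
tensor grid mapped through the Cholesky factor of the factor correlation
matrix. Model comparison uses AIC, BIC and chi-square likelihood-ratio tests
for nested pairs, and a leave-one-domain-out ablation quantifies each
domain's contribution beyond the general factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from ._graded import category_logprobs_eta, collapse_categories
from ._quad import gh_normal, log_sigmoid, norm_grid, sigmoid
from .datasets import DomainMap, ItemResponseMatrix, SeverityMatrix
from .tables import PersonScoreTable

NORMAL_METRIC_D = 1.702  # logit-to-probit slope conversion for loadings

_NESTED = {
    ("unidimensional", "bifactor"),
    ("unidimensional", "correlated_factors"),
}

STRUCTURES = ("unidimensional", "correlated_factors", "bifactor")


@dataclass
class ModelSpec:
    """What to fit and how hard to integrate."""

    structure: str = "unidimensional"
    link: str = "binary_2pl"  # or "graded"
    n_quad: int = 101  # unidimensional grid / bifactor general factor
    n_quad_specific: int = 21  # bifactor specific factors
    n_quad_per_dim: int = 5  # correlated-factors tensor grid
    max_iter: int = 300
    tol: float = 1e-4  # absolute log-likelihood change at convergence
    ridge: float = 1e-4  # weak L2 penalty on slopes/intercepts
    degenerate_ridge: float = 0.05  # penalty for all-0/all-1 items
    equal_slopes: bool = False  # Rasch-like constraint (unidimensional only)
    drop_specific: tuple = ()  # domains whose specific factor is removed

    def validate(self, dmap: DomainMap | None) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.link not in ("binary_2pl", "graded"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.structure != "unidimensional" and dmap is None:
            raise ValueError(f"{self.structure} requires a domain map")
        if self.equal_slopes and self.structure != "unidimensional":
            raise ValueError("equal_slopes applies to the unidimensional model")


@dataclass
class LatentParams:
    """Item parameters of one latent-structure model.

    Binary link: item j has linear predictor
    ``a_general_j*theta_g [+ a_specific_j*theta_d] + intercept_j`` (for the
    correlated model, theta_g means the item's own domain factor). Graded
    link: ``intercepts`` holds one increasing array of category intercepts
    d_k per item instead.
    """

    structure: str
    link: str
    item_ids: list
    a_general: np.ndarray
    intercepts: object  # (J,) array (binary) or list of arrays (graded)
    a_specific: np.ndarray | None = None
    corr: np.ndarray | None = None  # factor correlations (correlated model)
    domains: list | None = None  # domain order used for indices
    item_domain_index: np.ndarray | None = None
    category_maps: list | None = None  # graded link: collapse records

    def difficulty(self) -> np.ndarray:
        """b_j = -c_j / a_j for the binary link."""
        if self.link != "binary_2pl":
            raise ValueError("difficulty is defined for the binary link")
        return -np.asarray(self.intercepts) / self.a_general


@dataclass
class FitResult:
    params: LatentParams
    loglik: float
    n_parameters: int
    n_persons: int
    converged: bool
    n_iter: int
    spec: ModelSpec
    loglik_path: list = field(default_factory=list)
    ascent_violations: int = 0
    degenerate_items: list = field(default_factory=list)
    data_fingerprint: tuple | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_parameters

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_parameters * np.log(self.n_persons)


# ---------------------------------------------------------------------------
# data preparation


def _binary_indicators(values: np.ndarray):
    y1 = (values == 1.0).astype(float)
    y0 = (values == 0.0).astype(float)
    return y1, y0


def _prepare_graded(values: np.ndarray):
    """Collapse each column to contiguous categories; return codes + maps."""
    out = np.empty_like(values)
    n_cats, maps = [], []
    for j in range(values.shape[1]):
        col, mapping = collapse_categories(values[:, j])
        out[:, j] = col
        n_cats.append(len(mapping))
        maps.append(mapping)
    return out, n_cats, maps


def _graded_block_loglik(values, item_idx, eta_grid, d_list):
    """(n, G) log-likelihood of a block of graded items.

    ``eta_grid``: (G, J_block) linear predictors; ``d_list``: intercept arrays.
    """
    n = values.shape[0]
    G = eta_grid.shape[0]
    total = np.zeros((n, G))
    for pos, j in enumerate(item_idx):
        logp = category_logprobs_eta(eta_grid[:, pos], d_list[pos])  # (G, C)
        col = values[:, j]
        for k in range(logp.shape[1]):
            mask = col == k
            if mask.any():
                total[mask] += logp[:, k]
    return total


# ---------------------------------------------------------------------------
# M-step solvers


def _ridge_penalty(ridge, a_general, intercepts, a_specific=None):
    """0.5 * sum_j ridge_j * ||item j parameters||^2.

    EM monotonicity holds for the penalized objective the M-step maximizes;
    ascent is therefore checked on loglik minus this penalty.
    """
    a_general = np.asarray(a_general, dtype=float)
    per_item = a_general**2
    if a_specific is not None:
        per_item = per_item + np.asarray(a_specific, dtype=float) ** 2
    if isinstance(intercepts, (list, tuple)):
        per_item = per_item + np.array([float(np.sum(np.square(d))) for d in intercepts])
    else:
        per_item = per_item + np.asarray(intercepts, dtype=float) ** 2
    return 0.5 * float(np.sum(ridge * per_item))


def _newton_binary(r, nq, X, params0, ridge, max_steps=6, gtol=1e-5):
    """Weighted logistic regression on a grid, one item per column.

    r, nq: (G, J) expected endorsements / exposures; X: (G, P) design;
    params0: (P, J). Ridge is a per-item vector (J,). Steps are backtracked
    per item so the penalized expected log-likelihood never decreases: a few
    monotone ascent steps per M-step give a generalized EM that keeps the
    overall iteration monotone without solving each inner problem exactly.
    """

    def objective(par):
        eta = X @ par
        return (
            (r * log_sigmoid(eta)).sum(axis=0)
            + ((nq - r) * log_sigmoid(-eta)).sum(axis=0)
            - 0.5 * ridge * (par**2).sum(axis=0)
        )

    params = params0.copy()
    P = X.shape[1]
    eye = np.eye(P)
    obj = objective(params)
    for _ in range(max_steps):
        p = sigmoid(X @ params)
        grad = X.T @ (r - nq * p) - ridge[None, :] * params
        if np.max(np.abs(grad)) < gtol:
            break
        w = nq * p * (1.0 - p) + 1e-12
        H = np.einsum("gp,gj,gq->jpq", X, w, X) + ridge[:, None, None] * eye
        step = np.clip(np.linalg.solve(H, grad.T[:, :, None])[..., 0].T, -2.0, 2.0)
        for _bt in range(12):
            obj_new = objective(params + step)
            worse = obj_new < obj
            if not worse.any():
                break
            step[:, worse] *= 0.5
        improved = obj_new >= obj
        params[:, improved] = params[:, improved] + step[:, improved]
        obj = np.where(improved, obj_new, obj)
    return params


def _newton_equal_slope(r, nq, x, a, c, ridge, rounds=8):
    """Common slope a, per-item intercepts c (Rasch-like 2PL)."""
    for _ in range(rounds):
        eta = a * x[:, None] + c[None, :]
        p = sigmoid(eta)
        # intercepts
        g_c = (r - nq * p).sum(axis=0) - ridge * c
        h_c = (nq * p * (1 - p)).sum(axis=0) + ridge + 1e-12
        c = c + np.clip(g_c / h_c, -2.0, 2.0)
        # common slope
        eta = a * x[:, None] + c[None, :]
        p = sigmoid(eta)
        g_a = float((x[:, None] * (r - nq * p)).sum()) - ridge.mean() * a
        h_a = float((x[:, None] ** 2 * nq * p * (1 - p)).sum()) + 1e-12
        a = a + float(np.clip(g_a / h_a, -1.0, 1.0))
    return a, c


def _mstep_graded_item(r_gk, tvals, slopes0, d0, ridge):
    """Maximize expected complete-data log-likelihood for one graded item.

    r_gk: (G, C) expected category counts at grid points; tvals: (G, P)
    latent design (no intercept column); slopes0: (P,), d0: increasing (C-1,).
    Parameterized as (slopes, d_1, log increments) for ordering.
    """
    C = r_gk.shape[1]
    P = tvals.shape[1]
    inc0 = np.clip(np.diff(d0), 1e-4, None)
    x0 = np.concatenate([slopes0, [d0[0]], np.log(inc0)])

    def negll(x):
        slopes = x[:P]
        d = x[P] + np.concatenate([[0.0], np.cumsum(np.exp(x[P + 1 :]))])
        eta = tvals @ slopes
        logp = category_logprobs_eta(eta, d)
        return -float(np.sum(r_gk * logp)) + 0.5 * ridge * float(
            np.sum(slopes**2) + np.sum(d**2)
        )

    res = optimize.minimize(negll, x0, method="L-BFGS-B")
    slopes = res.x[:P]
    d = res.x[P] + np.concatenate([[0.0], np.cumsum(np.exp(res.x[P + 1 :]))])
    return slopes, d


# ---------------------------------------------------------------------------
# unidimensional model


def _uni_grid_loglik(params: LatentParams, values, x):
    """(n, Q) log-likelihood over the 1-D grid."""
    if params.link == "binary_2pl":
        eta = np.outer(x, params.a_general) + np.asarray(params.intercepts)[None, :]
        y1, y0 = _binary_indicators(values)
        return y1 @ log_sigmoid(eta).T + y0 @ log_sigmoid(-eta).T
    eta = np.outer(x, params.a_general)
    return _graded_block_loglik(
        values, range(values.shape[1]), eta, list(params.intercepts)
    )


def _fit_unidimensional(values, item_ids, spec, init=None):
    n, J = values.shape
    x, w = norm_grid(spec.n_quad)
    logw = np.log(w)
    graded = spec.link == "graded"
    if graded:
        values, n_cats, cat_maps = _prepare_graded(values)
    y1, y0 = _binary_indicators(values)
    obs = ~np.isnan(values)
    rates = np.clip(
        np.nansum(values == 1, axis=0) / np.maximum(obs.sum(axis=0), 1), 0.02, 0.98
    )
    degenerate = [
        item_ids[j]
        for j in range(J)
        if obs[:, j].any()
        and (np.nanmin(values[:, j]) == np.nanmax(values[:, j]))
    ]
    ridge = np.full(J, spec.ridge)
    for j, iid in enumerate(item_ids):
        if iid in degenerate:
            ridge[j] = spec.degenerate_ridge
    if degenerate:
        warnings.warn(
            f"items with no response variation penalized toward zero slope: "
            f"{degenerate}",
            stacklevel=3,
        )

    if init is not None:
        a = init.a_general.copy()
        d_list = (
            [np.asarray(d, dtype=float).copy() for d in init.intercepts]
            if graded
            else None
        )
        c = None if graded else np.asarray(init.intercepts, dtype=float).copy()
    else:
        a = np.ones(J)
        if graded:
            d_list = []
            for j in range(J):
                C = n_cats[j]
                # start thresholds from observed cumulative proportions
                col = values[obs[:, j], j]
                cum = np.array([(col >= k).mean() for k in range(1, C)])
                d_list.append(-np.log(np.clip(cum, 0.02, 0.98) ** -1 - 1))
            d_list = [np.sort(d) for d in d_list]
        else:
            c = np.log(rates / (1 - rates))

    ll_path = []
    violations = 0
    converged = False
    it = 0
    for it in range(1, spec.max_iter + 1):
        params = LatentParams(
            "unidimensional",
            spec.link,
            item_ids,
            a,
            d_list if graded else c,
        )
        LL = _uni_grid_loglik(params, values, x)
        person_ll = logsumexp(LL + logw[None, :], axis=1)
        ll = float(person_ll.sum())
        pen = ll - _ridge_penalty(ridge, a, d_list if graded else c)
        if ll_path and pen < pen_prev - 1e-8 * max(1.0, abs(pen)):
            violations += 1
        pen_prev = pen
        if ll_path and abs(ll - ll_path[-1]) < spec.tol:
            ll_path.append(ll)
            converged = True
            break
        ll_path.append(ll)
        post = np.exp(LL + logw[None, :] - person_ll[:, None])  # (n, Q)
        if graded:
            for j in range(J):
                C = n_cats[j]
                r_gk = np.stack(
                    [post[values[:, j] == k].sum(axis=0) for k in range(C)], axis=1
                )
                s, d = _mstep_graded_item(
                    r_gk, x[:, None], np.array([a[j]]), d_list[j], ridge[j]
                )
                a[j] = abs(s[0])
                d_list[j] = d
        else:
            r = post.T @ y1  # (Q, J)
            nq = post.T @ obs.astype(float)
            if spec.equal_slopes:
                a_common, c = _newton_equal_slope(
                    r, nq, x, float(a[0]), c, ridge
                )
                a = np.full(J, a_common)
            else:
                X = np.column_stack([x, np.ones_like(x)])
                packed = _newton_binary(r, nq, X, np.vstack([a, c]), ridge)
                a, c = packed[0], packed[1]
    params = LatentParams(
        "unidimensional",
        spec.link,
        item_ids,
        a,
        d_list if graded else c,
        category_maps=cat_maps if graded else None,
    )
    if graded:
        n_par = sum(1 + len(d) for d in d_list)
    else:
        n_par = (J + 1) if spec.equal_slopes else 2 * J
    return params, ll_path, n_par, converged, it, violations, degenerate


# ---------------------------------------------------------------------------
# bifactor model


def _bifactor_structures(spec, dmap, item_ids):
    domains = dmap.domains
    dj = dmap.domain_index(item_ids)
    keep = [d for d in domains if d not in spec.drop_specific]
    items_by_domain = {
        d: np.where(dj == k)[0] for k, d in enumerate(domains) if d in keep
    }
    dropped_items = np.array(
        [
            j
            for k, d in enumerate(domains)
            if d not in keep
            for j in np.where(dj == k)[0]
        ],
        dtype=int,
    )
    return domains, dj, items_by_domain, dropped_items


def _bifactor_person_loglik(params, spec, values, x0, logw0, xs, logws, parts):
    """Person log-liks plus per-domain pieces needed by the E-step."""
    domains, dj, items_by_domain, dropped_items = parts
    n = values.shape[0]
    Q0, Qs = len(x0), len(xs)
    graded = params.link == "graded"
    if not graded:
        y1, y0 = _binary_indicators(values)
    A = {}
    M = {}
    total = np.zeros((n, Q0))
    for d, idx in items_by_domain.items():
        a0 = params.a_general[idx]
        asp = params.a_specific[idx]
        eta = (
            x0[:, None, None] * a0[None, None, :]
            + xs[None, :, None] * asp[None, None, :]
        ).reshape(Q0 * Qs, len(idx))
        if graded:
            A_d = _graded_block_loglik(
                values, idx, eta, [params.intercepts[j] for j in idx]
            )
        else:
            eta = eta + np.asarray(params.intercepts)[idx][None, :]
            A_d = y1[:, idx] @ log_sigmoid(eta).T + y0[:, idx] @ log_sigmoid(-eta).T
        A_d = A_d.reshape(n, Q0, Qs)
        M_d = logsumexp(A_d + logws[None, None, :], axis=2)  # (n, Q0)
        A[d], M[d] = A_d, M_d
        total += M_d
    G_mat = None
    if len(dropped_items):
        idx = dropped_items
        eta = x0[:, None] * params.a_general[idx][None, :]
        if graded:
            G_mat = _graded_block_loglik(
                values, idx, eta, [params.intercepts[j] for j in idx]
            )
        else:
            eta = eta + np.asarray(params.intercepts)[idx][None, :]
            G_mat = y1[:, idx] @ log_sigmoid(eta).T + y0[:, idx] @ log_sigmoid(-eta).T
        total += G_mat
    person_ll = logsumexp(total + logw0[None, :], axis=1)
    return person_ll, total, A, M, G_mat


def _fit_bifactor(values, item_ids, dmap, spec, init=None):
    n, J = values.shape
    x0, w0 = norm_grid(spec.n_quad)
    xs, ws = norm_grid(spec.n_quad_specific)
    logw0, logws = np.log(w0), np.log(ws)
    graded = spec.link == "graded"
    if graded:
        values, n_cats, cat_maps = _prepare_graded(values)
    obs = ~np.isnan(values)
    parts = _bifactor_structures(spec, dmap, item_ids)
    domains, dj, items_by_domain, dropped_items = parts
    y1 = (values == 1.0).astype(float)

    degenerate = [
        item_ids[j]
        for j in range(J)
        if obs[:, j].any() and np.nanmin(values[:, j]) == np.nanmax(values[:, j])
    ]
    ridge = np.full(J, spec.ridge)
    for j, iid in enumerate(item_ids):
        if iid in degenerate:
            ridge[j] = spec.degenerate_ridge
    if degenerate:
        warnings.warn(f"degenerate items penalized: {degenerate}", stacklevel=3)

    if init is not None:
        a0 = init.a_general.copy()
        asp = (
            init.a_specific.copy()
            if init.a_specific is not None
            else np.full(J, 0.5)
        )
        if graded:
            d_list = [np.asarray(d, dtype=float).copy() for d in init.intercepts]
        else:
            c = np.asarray(init.intercepts, dtype=float).copy()
    else:
        a0 = np.ones(J)
        asp = np.full(J, 0.5)
        if graded:
            d_list = []
            for j in range(J):
                col = values[obs[:, j], j]
                C = n_cats[j]
                cum = np.array([(col >= k).mean() for k in range(1, C)])
                d_list.append(np.sort(-np.log(np.clip(cum, 0.02, 0.98) ** -1 - 1)))
        else:
            rates = np.clip(
                np.nansum(values == 1, axis=0) / np.maximum(obs.sum(axis=0), 1),
                0.02,
                0.98,
            )
            c = np.log(rates / (1 - rates))
    if len(dropped_items):
        asp[dropped_items] = 0.0

    ll_path, violations, converged = [], 0, False
    it = 0
    for it in range(1, spec.max_iter + 1):
        params = LatentParams(
            "bifactor",
            spec.link,
            item_ids,
            a0,
            d_list if graded else c,
            a_specific=asp,
            domains=list(domains),
            item_domain_index=dj,
        )
        person_ll, total, A, M, G_mat = _bifactor_person_loglik(
            params, spec, values, x0, logw0, xs, logws, parts
        )
        ll = float(person_ll.sum())
        pen = ll - _ridge_penalty(ridge, a0, d_list if graded else c, asp)
        if ll_path and pen < pen_prev - 1e-8 * max(1.0, abs(pen)):
            violations += 1
        pen_prev = pen
        if ll_path and abs(ll - ll_path[-1]) < spec.tol:
            ll_path.append(ll)
            converged = True
            break
        ll_path.append(ll)
        Q0, Qs = len(x0), len(xs)
        for d, idx in items_by_domain.items():
            logpost = (
                logw0[None, :, None]
                + (total - M[d])[:, :, None]
                + logws[None, None, :]
                + A[d]
                - person_ll[:, None, None]
            )
            w_joint = np.exp(logpost).reshape(n, Q0 * Qs)
            X = np.column_stack(
                [
                    np.repeat(x0, Qs),
                    np.tile(xs, Q0),
                    np.ones(Q0 * Qs),
                ]
            )
            if graded:
                for pos, j in enumerate(idx):
                    C = n_cats[j]
                    r_gk = np.stack(
                        [w_joint[values[:, j] == k].sum(axis=0) for k in range(C)],
                        axis=1,
                    )
                    s, dpar = _mstep_graded_item(
                        r_gk,
                        X[:, :2],
                        np.array([a0[j], asp[j]]),
                        d_list[j],
                        ridge[j],
                    )
                    a0[j], asp[j] = s[0], s[1]
                    d_list[j] = dpar
            else:
                r = w_joint.T @ y1[:, idx]
                nq = w_joint.T @ obs[:, idx].astype(float)
                packed = _newton_binary(
                    r, nq, X, np.vstack([a0[idx], asp[idx], c[idx]]), ridge[idx]
                )
                a0[idx], asp[idx], c[idx] = packed
        if len(dropped_items):
            idx = dropped_items
            wq0 = np.exp(logw0[None, :] + total - person_ll[:, None])
            X = np.column_stack([x0, np.ones(Q0)])
            if graded:
                for j in idx:
                    C = n_cats[j]
                    r_gk = np.stack(
                        [wq0[values[:, j] == k].sum(axis=0) for k in range(C)],
                        axis=1,
                    )
                    s, dpar = _mstep_graded_item(
                        r_gk, x0[:, None], np.array([a0[j]]), d_list[j], ridge[j]
                    )
                    a0[j] = s[0]
                    d_list[j] = dpar
            else:
                r = wq0.T @ y1[:, idx]
                nq = wq0.T @ obs[:, idx].astype(float)
                packed = _newton_binary(
                    r, nq, X, np.vstack([a0[idx], c[idx]]), ridge[idx]
                )
                a0[idx], c[idx] = packed

    # sign identification: specific factors are symmetric, fix each domain's
    # specific slopes to sum positive
    for d, idx in items_by_domain.items():
        if asp[idx].sum() < 0:
            asp[idx] = -asp[idx]
    params = LatentParams(
        "bifactor",
        spec.link,
        item_ids,
        a0,
        d_list if graded else c,
        a_specific=asp,
        domains=list(domains),
        item_domain_index=dj,
        category_maps=cat_maps if graded else None,
    )
    if graded:
        n_par = sum(
            (1 if j in dropped_items else 2) + len(d_list[j]) for j in range(J)
        )
    else:
        n_par = 3 * J - len(dropped_items)
    return params, ll_path, n_par, converged, it, violations, degenerate


# ---------------------------------------------------------------------------
# correlated factors model


def _nearest_corr(R: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Symmetrize, floor the eigenvalues, and renormalize to unit diagonal.

    Keeps the factor correlation matrix safely positive definite even when
    the data drive the correlations toward the unidimensional boundary.
    """
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < floor:
        R = (vecs * np.clip(vals, floor, None)) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return R


class _CorrGrid:
    """Tensor grid for correlated factors with prefix-structured coordinates.

    Domains are assigned to Cholesky coordinate positions in order of
    descending item count, so the domains with most items sit on coordinates
    whose grid values take fewest distinct prefixes (cheapest likelihood
    blocks).
    """

    def __init__(self, dmap, item_ids, n_nodes):
        self.domains = dmap.domains
        dj_map = dmap.domain_index(item_ids)
        counts = [(d, int(np.sum(dj_map == k))) for k, d in enumerate(self.domains)]
        order = sorted(range(len(counts)), key=lambda k: -counts[k][1])
        self.pos_of_domain = {self.domains[k]: p for p, k in enumerate(order)}
        self.domain_at_pos = [self.domains[k] for k in order]
        self.D = len(self.domains)
        self.Q = n_nodes
        self.x, self.w = gh_normal(n_nodes)
        self.G = n_nodes**self.D
        self.items_at_pos = [
            np.where(dj_map == self.domains.index(d))[0] for d in self.domain_at_pos
        ]
        logw1 = np.log(self.w)
        lw = np.zeros(1)
        for _ in range(self.D):
            lw = (lw[:, None] + logw1[None, :]).ravel()
        self.logw_full = lw

    def prefix_values(self, L):
        """Per position p: t_p on the Q^(p+1) prefix grid (position-ordered L)."""
        vals = []
        prefix = np.zeros((1, 0))
        for p in range(self.D):
            prefix = np.concatenate(
                [
                    np.repeat(prefix, self.Q, axis=0),
                    np.tile(self.x, prefix.shape[0])[:, None],
                ],
                axis=1,
            )
            vals.append(prefix @ L[p, : p + 1])
        return vals

    def t_full(self, tvals):
        """(G, D) latent values on the full grid, columns in position order."""
        out = np.empty((self.G, self.D))
        for p, tv in enumerate(tvals):
            out[:, p] = np.repeat(tv, self.G // len(tv))
        return out


def _fit_correlated(values, item_ids, dmap, spec, init=None):
    n, J = values.shape
    grid = _CorrGrid(dmap, item_ids, spec.n_quad_per_dim)
    graded = spec.link == "graded"
    if graded:
        values, n_cats, cat_maps = _prepare_graded(values)
    obs = ~np.isnan(values)
    y1 = (values == 1.0).astype(float)
    y0 = (values == 0.0).astype(float)
    D = grid.D

    degenerate = [
        item_ids[j]
        for j in range(J)
        if obs[:, j].any() and np.nanmin(values[:, j]) == np.nanmax(values[:, j])
    ]
    ridge = np.full(J, spec.ridge)
    for j, iid in enumerate(item_ids):
        if iid in degenerate:
            ridge[j] = spec.degenerate_ridge
    if degenerate:
        warnings.warn(f"degenerate items penalized: {degenerate}", stacklevel=3)

    if init is not None:
        a = init.a_general.copy()
        R = init.corr.copy() if init.corr is not None else np.eye(D)
        if graded:
            d_list = [np.asarray(d, dtype=float).copy() for d in init.intercepts]
        else:
            c = np.asarray(init.intercepts, dtype=float).copy()
    else:
        a = np.ones(J)
        R = np.full((D, D), 0.3) + 0.7 * np.eye(D)
        if graded:
            d_list = []
            for j in range(J):
                col = values[obs[:, j], j]
                C = n_cats[j]
                cum = np.array([(col >= k).mean() for k in range(1, C)])
                d_list.append(np.sort(-np.log(np.clip(cum, 0.02, 0.98) ** -1 - 1)))
        else:
            rates = np.clip(
                np.nansum(values == 1, axis=0) / np.maximum(obs.sum(axis=0), 1),
                0.02,
                0.98,
            )
            c = np.log(rates / (1 - rates))

    ll_path, violations, converged = [], 0, False
    it = 0
    for it in range(1, spec.max_iter + 1):
        # R is in domain order; reorder to position order for the grid
        perm = [grid.domains.index(d) for d in grid.domain_at_pos]
        Rp = R[np.ix_(perm, perm)]
        L = np.linalg.cholesky(Rp + 1e-10 * np.eye(D))
        tvals = grid.prefix_values(L)
        # per-position likelihood blocks on prefix grids
        LLfull = np.zeros((n, grid.G))
        blocks = []
        for p in range(D):
            idx = grid.items_at_pos[p]
            tv = tvals[p]
            if graded:
                eta = tv[:, None] * a[idx][None, :]
                A_p = _graded_block_loglik(
                    values, idx, eta, [d_list[j] for j in idx]
                )
            else:
                eta = tv[:, None] * a[idx][None, :] + c[idx][None, :]
                A_p = (
                    y1[:, idx] @ log_sigmoid(eta).T
                    + y0[:, idx] @ log_sigmoid(-eta).T
                )
            blocks.append(A_p)
            LLfull.reshape(n, len(tv), -1)[:] += A_p[:, :, None]
        # one exp pass yields both the person log-liks and posterior weights
        LLfull += grid.logw_full[None, :]
        mx = LLfull.max(axis=1)
        np.exp(LLfull - mx[:, None], out=LLfull)
        w_full = LLfull
        norm = w_full.sum(axis=1)
        person_ll = mx + np.log(norm)
        w_full /= norm[:, None]
        ll = float(person_ll.sum())
        pen = ll - _ridge_penalty(ridge, a, d_list if graded else c)
        if ll_path and pen < pen_prev - 1e-8 * max(1.0, abs(pen)):
            violations += 1
        pen_prev = pen
        if ll_path and abs(ll - ll_path[-1]) < spec.tol:
            ll_path.append(ll)
            converged = True
            break
        ll_path.append(ll)
        # latent covariance update from posterior second moments
        colw = w_full.sum(axis=0)
        T = grid.t_full(tvals)
        S = T.T @ (colw[:, None] * T) / n
        sds = np.sqrt(np.clip(np.diag(S), 1e-6, None))
        Rp_new = _nearest_corr(S / np.outer(sds, sds))
        # item M-steps on prefix grids (rescale slopes for the re-standardized
        # factor variances)
        for p in range(D):
            idx = grid.items_at_pos[p]
            tv = tvals[p]
            w_pref = w_full.reshape(n, len(tv), -1).sum(axis=2)
            if graded:
                for j in idx:
                    C = n_cats[j]
                    r_gk = np.stack(
                        [w_pref[values[:, j] == k].sum(axis=0) for k in range(C)],
                        axis=1,
                    )
                    s, dpar = _mstep_graded_item(
                        r_gk, tv[:, None], np.array([a[j]]), d_list[j], ridge[j]
                    )
                    a[j] = abs(s[0])
                    d_list[j] = dpar
            else:
                r = w_pref.T @ y1[:, idx]
                nq = w_pref.T @ obs[:, idx].astype(float)
                X = np.column_stack([tv, np.ones(len(tv))])
                packed = _newton_binary(
                    r, nq, X, np.vstack([a[idx], c[idx]]), ridge[idx]
                )
                a[idx], c[idx] = packed
            a[idx] = a[idx] * sds[p]
        inv = np.argsort(perm)
        R = Rp_new[np.ix_(inv, inv)]

    dj_map = dmap.domain_index(item_ids)
    params = LatentParams(
        "correlated_factors",
        spec.link,
        item_ids,
        a,
        d_list if graded else c,
        corr=R,
        domains=list(grid.domains),
        item_domain_index=dj_map,
        category_maps=cat_maps if graded else None,
    )
    if graded:
        n_par = sum(1 + len(d_list[j]) for j in range(J)) + D * (D - 1) // 2
    else:
        n_par = 2 * J + D * (D - 1) // 2
    return params, ll_path, n_par, converged, it, violations, degenerate


# ---------------------------------------------------------------------------
# public API


def marginal_loglik(
    params: LatentParams,
    data: ItemResponseMatrix | SeverityMatrix,
    dmap: DomainMap | None = None,
    spec: ModelSpec | None = None,
) -> float:
    """Marginal log-likelihood of ``data`` at the given parameters.

    Missing entries are skipped in each person's conditional likelihood
    product. The integral uses the quadrature sizes in ``spec`` (defaults
    match fitting).
    """
    spec = spec or ModelSpec(structure=params.structure, link=params.link)
    if not np.all(np.isfinite(np.asarray(params.a_general, dtype=float))):
        raise ValueError("non-finite slope parameter")
    values = data.values
    if params.link == "graded":
        values, _, _ = _prepare_graded(values)
    if params.structure == "unidimensional":
        x, w = norm_grid(spec.n_quad)
        LL = _uni_grid_loglik(params, values, x)
        return float(logsumexp(LL + np.log(w)[None, :], axis=1).sum())
    if dmap is None:
        raise ValueError("domain map required for multidimensional structures")
    if params.structure == "bifactor":
        x0, w0 = norm_grid(spec.n_quad)
        xs, ws = norm_grid(spec.n_quad_specific)
        parts = _bifactor_structures(spec, dmap, params.item_ids)
        person_ll, *_ = _bifactor_person_loglik(
            params, spec, values, x0, np.log(w0), xs, np.log(ws), parts
        )
        return float(person_ll.sum())
    # correlated factors
    grid = _CorrGrid(dmap, params.item_ids, spec.n_quad_per_dim)
    D = grid.D
    perm = [grid.domains.index(d) for d in grid.domain_at_pos]
    R = params.corr if params.corr is not None else np.eye(D)
    L = np.linalg.cholesky(R[np.ix_(perm, perm)] + 1e-10 * np.eye(D))
    tvals = grid.prefix_values(L)
    n = values.shape[0]
    y1 = (values == 1.0).astype(float)
    y0 = (values == 0.0).astype(float)
    LLfull = np.zeros((n, grid.G))
    a = params.a_general
    for p in range(D):
        idx = grid.items_at_pos[p]
        tv = tvals[p]
        if params.link == "graded":
            eta = tv[:, None] * a[idx][None, :]
            A_p = _graded_block_loglik(
                values, idx, eta, [params.intercepts[j] for j in idx]
            )
        else:
            eta = tv[:, None] * a[idx][None, :] + np.asarray(params.intercepts)[
                idx
            ][None, :]
            A_p = y1[:, idx] @ log_sigmoid(eta).T + y0[:, idx] @ log_sigmoid(-eta).T
        LLfull.reshape(n, len(tv), -1)[:] += A_p[:, :, None]
    return float(logsumexp(LLfull + grid.logw_full[None, :], axis=1).sum())


def fit_latent_model(
    data: ItemResponseMatrix | SeverityMatrix,
    dmap: DomainMap | None,
    spec: ModelSpec,
    init: LatentParams | None = None,
) -> FitResult:
    """Fit one latent-structure model by EM over fixed quadrature grids.

    Deterministic given data, spec and starting values; non-convergence
    within ``max_iter`` is flagged on the result rather than raised.
    """
    spec.validate(dmap)
    values = data.values
    item_ids = list(data.item_ids)
    if spec.structure == "unidimensional":
        out = _fit_unidimensional(values, item_ids, spec, init=init)
    elif spec.structure == "bifactor":
        out = _fit_bifactor(values, item_ids, dmap, spec, init=init)
    else:
        out = _fit_correlated(values, item_ids, dmap, spec, init=init)
    params, ll_path, n_par, converged, it, violations, degenerate = out
    if not converged:
        warnings.warn(
            f"{spec.structure} fit did not converge in {it} iterations "
            f"(last change {abs(ll_path[-1] - ll_path[-2]):.3g})",
            stacklevel=2,
        )
    fp = (values.shape[0], values.shape[1], float(np.nansum(values)))
    return FitResult(
        params=params,
        loglik=ll_path[-1],
        n_parameters=n_par,
        n_persons=values.shape[0],
        converged=converged,
        n_iter=it,
        spec=spec,
        loglik_path=ll_path,
        ascent_violations=violations,
        degenerate_items=degenerate,
        data_fingerprint=fp,
    )


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Fit-index table with deltas vs the best model and LRTs for nested pairs."""
    if len({f.n_persons for f in fits}) != 1:
        raise ValueError("fits are not on identical data (n_persons differs)")
    if len({f.data_fingerprint for f in fits if f.data_fingerprint}) > 1:
        raise ValueError("fits are not on identical data")
    rows = []
    best_aic = min(f.aic for f in fits)
    best_bic = min(f.bic for f in fits)
    by_structure = {f.params.structure: f for f in fits}
    for f in fits:
        s = f.params.structure
        lrt_stat = lrt_df = lrt_p = np.nan
        lrt_vs = ""
        for small, big in _NESTED:
            if s == big and small in by_structure:
                f0 = by_structure[small]
                lrt_stat = max(0.0, -2.0 * (f0.loglik - f.loglik))
                lrt_df = f.n_parameters - f0.n_parameters
                lrt_p = float(stats.chi2.sf(lrt_stat, lrt_df)) if lrt_df > 0 else 1.0
                if lrt_stat == 0.0:
                    lrt_p = 1.0
                lrt_vs = small
        rows.append(
            {
                "structure": s,
                "loglik": f.loglik,
                "n_parameters": f.n_parameters,
                "aic": f.aic,
                "bic": f.bic,
                "delta_aic": f.aic - best_aic,
                "delta_bic": f.bic - best_bic,
                "lrt_vs": lrt_vs,
                "lrt_stat": lrt_stat,
                "lrt_df": lrt_df,
                "lrt_p": lrt_p,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)


def leave_one_domain_out(
    data: ItemResponseMatrix,
    dmap: DomainMap,
    spec: ModelSpec,
    full_fit: FitResult | None = None,
) -> pd.DataFrame:
    """Refit the hierarchical model with each domain's specific factor removed.

    For each domain the items keep their general-factor loading but lose the
    specific one; the log-likelihood drop and a chi-square LRT against the
    full model quantify the domain's contribution beyond the general trait.
    Ablated fits warm-start from the full solution. Rows are sorted by drop.
    """
    if spec.structure != "bifactor":
        raise ValueError("leave-one-domain-out applies to the bifactor structure")
    if full_fit is None:
        full_fit = fit_latent_model(data, dmap, spec)
    rows = []
    for d in dmap.domains:
        spec_d = replace(spec, drop_specific=(d,))
        init = replace(
            full_fit.params,
            a_specific=full_fit.params.a_specific.copy(),
        )
        fit_d = fit_latent_model(data, dmap, spec_d, init=init)
        drop = full_fit.loglik - fit_d.loglik
        df = full_fit.n_parameters - fit_d.n_parameters
        stat = max(0.0, 2.0 * drop)
        rows.append(
            {
                "domain": d,
                "loglik_full": full_fit.loglik,
                "loglik_ablated": fit_d.loglik,
                "loglik_drop": drop,
                "lrt_stat": stat,
                "lrt_df": df,
                "lrt_p": float(stats.chi2.sf(stat, df)),
                "converged": fit_d.converged,
            }
        )
    out = pd.DataFrame(rows).sort_values("loglik_drop", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def standardized_loadings(
    fit: FitResult, significant: float = 0.35
) -> pd.DataFrame:
    """Normal-metric standardized loadings from logit slopes.

    lambda_jk = (a_jk / D*) / sqrt(1 + sum_k (a_jk / D*)^2) with D* = 1.702,
    so each |loading| < 1 and the communality is the sum of squared loadings.
    ``significant`` flags specific loadings at or above the given threshold.
    """
    p = fit.params
    ag = np.asarray(p.a_general, dtype=float) / NORMAL_METRIC_D
    asp = (
        np.asarray(p.a_specific, dtype=float) / NORMAL_METRIC_D
        if p.a_specific is not None
        else np.zeros_like(ag)
    )
    denom = np.sqrt(1.0 + ag**2 + asp**2)
    lam_g = ag / denom
    lam_s = asp / denom
    df = pd.DataFrame(
        {
            "item_id": p.item_ids,
            "loading_general": lam_g,
            "loading_specific": lam_s,
            "communality": lam_g**2 + lam_s**2,
            "specific_significant": np.abs(lam_s) >= significant,
        }
    )
    if p.item_domain_index is not None and p.domains is not None:
        df.insert(1, "domain", [p.domains[k] for k in p.item_domain_index])
    return df


def eap_scores_binary(
    params: LatentParams, data: ItemResponseMatrix, n_quad: int = 61
) -> PersonScoreTable:
    """EAP person scores under a fitted unidimensional binary model."""
    if params.structure != "unidimensional" or params.link != "binary_2pl":
        raise ValueError("EAP scoring here expects a unidimensional binary model")
    x, w = norm_grid(n_quad)
    a = np.asarray(params.a_general, dtype=float)
    equal_slopes = np.ptp(a) == 0.0 and not np.isnan(data.values).any()
    if equal_slopes:
        # Rasch-type sufficiency: the posterior depends on the data only
        # through the endorsement count, so score the sufficient statistic
        # directly (ties in the raw count stay exact ties in the score).
        eta = np.outer(x, a) + np.asarray(params.intercepts)[None, :]
        base = log_sigmoid(-eta).sum(axis=1)  # (Q,)
        counts = (data.values == 1.0).sum(axis=1)
        LL = a[0] * np.outer(counts, x) + base[None, :]
    else:
        LL = _uni_grid_loglik(params, data.values, x)
    logpost = LL + np.log(w)[None, :]
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    mean = post @ x
    sd = np.sqrt(np.clip(post @ x**2 - mean**2, 1e-12, None))
    flags = {}
    any_obs = (~np.isnan(data.values)).any(axis=1)
    endorsed = np.nansum(data.values == 1, axis=1)
    for i, pid in enumerate(data.person_ids):
        if not any_obs[i]:
            flags[pid] = "no_observed_responses"
        elif endorsed[i] == 0:
            flags[pid] = "zero_symptoms"
    return PersonScoreTable(list(data.person_ids), mean, sd, flags)
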