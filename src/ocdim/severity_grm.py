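"""Graded response model for the 10 clinician severity ratings.

Each 0-4 rating is modelled with one discrimination and four ordered
thresholds on a latent severity trait (standard normal). Fitting is marginal
maximum likelihood by EM over a one-dimensional normal-weighted grid;
not-administered entries are skipped. Standard errors come from the empirical
(outer-product-of-scores) information of the marginal likelihood. Person
scores are expected-a-posteriori means with posterior SDs as standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._graded import (
    category_logprobs_eta,
    category_probs,
    collapse_categories,
    pack_graded,
    unpack_graded,
)
from ._quad import norm_grid
from .datasets import SeverityMatrix
from .latent_models import _mstep_graded_item
from .tables import FLOAT_FMT, PersonScoreTable


@dataclass
class GradedItemParams:
    """One rating item: discrimination with SE, ordered thresholds with SEs."""

    item_id: str
    a: float
    thresholds: np.ndarray
    a_se: float = np.nan
    thresholds_se: np.ndarray | None = None
    category_map: dict = field(default_factory=dict)  # original -> fitted code
    flagged: str = ""

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.a <= 0:
            raise ValueError("discrimination must be positive")
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be non-decreasing")


def grm_category_probs(params: GradedItemParams, theta) -> np.ndarray:
    """P(Y = k | theta) for each category; last axis has C entries."""
    return category_probs(params.a, params.thresholds, theta)


@dataclass
class GRMFit:
    items: list  # of GradedItemParams
    loglik: float
    n_persons: int
    converged: bool
    n_iter: int

    @property
    def n_parameters(self) -> int:
        return sum(1 + len(p.thresholds) for p in self.items)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.items:
            row = {"item_id": p.item_id, "a": p.a, "a_se": p.a_se}
            for k in range(4):
                row[f"b{k + 1}"] = (
                    p.thresholds[k] if k < len(p.thresholds) else np.nan
                )
                se = (
                    p.thresholds_se[k]
                    if p.thresholds_se is not None and k < len(p.thresholds_se)
                    else np.nan
                )
                row[f"b{k + 1}_se"] = se
            row["flag"] = p.flagged
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def _grid_loglik(values, item_params, x):
    """(n, Q) log-likelihood over the grid; NaN entries skipped."""
    n = values.shape[0]
    total = np.zeros((n, len(x)))
    for j, p in enumerate(item_params):
        d = p.a * p.thresholds
        logp = category_logprobs_eta(p.a * x, d)  # (Q, C)
        col = values[:, j]
        for k in range(logp.shape[1]):
            mask = col == k
            if mask.any():
                total[mask] += logp[:, k]
    return total


def marginal_loglik_grm(items: list, sev: SeverityMatrix, n_quad: int = 61) -> float:
    """Marginal log-likelihood of the severity data at given item parameters."""
    x, w = norm_grid(n_quad)
    values = _recode(sev, items)
    LL = _grid_loglik(values, items, x)
    return float(logsumexp(LL + np.log(w)[None, :], axis=1).sum())


def _recode(sev: SeverityMatrix, items):
    """Select the fitted items' columns and apply their category remaps."""
    cols = []
    for p in items:
        j = sev.item_ids.index(p.item_id)
        col = sev.values[:, j].copy()
        if p.category_map:
            src = sev.values[:, j]
            for old, new in p.category_map.items():
                col[src == old] = new
        cols.append(col)
    return np.column_stack(cols)


def fit_grm(
    sev: SeverityMatrix,
    n_quad: int = 61,
    max_iter: int = 300,
    tol: float = 1e-5,
    ridge: float = 1e-4,
    compute_se: bool = True,
) -> GRMFit:
    """Marginal-ML fit of the graded response model by EM.

    Items whose internal categories are unobserved are collapsed downward
    with the remapping recorded on the item; an item with a single observed
    category is excluded with a warning. Items with near-zero discrimination
    or very large slope SEs are flagged rather than dropped.
    """
    values = sev.values.copy()
    n, J = values.shape
    keep, cat_maps, n_cats = [], [], []
    for j in range(J):
        col, mapping = collapse_categories(values[:, j])
        if len(mapping) < 2:
            warnings.warn(
                f"severity item {sev.item_ids[j]!r} has a single observed "
                "category and is excluded from the fit",
                stacklevel=2,
            )
            continue
        values[:, j] = col
        keep.append(j)
        cat_maps.append(mapping)
        n_cats.append(len(mapping))
    if not keep:
        raise ValueError("no severity item has two or more observed categories")
    values = values[:, keep]
    item_ids = [sev.item_ids[j] for j in keep]
    J = len(keep)
    x, w = norm_grid(n_quad)
    logw = np.log(w)
    obs = ~np.isnan(values)

    items = []
    for j in range(J):
        col = values[obs[:, j], j]
        C = n_cats[j]
        cum = np.array([(col >= k).mean() for k in range(1, C)])
        b0 = np.sort(-np.log(np.clip(cum, 0.02, 0.98) ** -1 - 1))
        b0 = b0 + np.arange(C - 1) * 1e-3  # break exact ties
        items.append(
            GradedItemParams(item_ids[j], 1.0, b0, category_map=cat_maps[j])
        )

    ll_path, converged = [], False
    it = 0
    for it in range(1, max_iter + 1):
        LL = _grid_loglik(values, items, x)
        person_ll = logsumexp(LL + logw[None, :], axis=1)
        ll = float(person_ll.sum())
        if ll_path and abs(ll - ll_path[-1]) < tol:
            ll_path.append(ll)
            converged = True
            break
        ll_path.append(ll)
        post = np.exp(LL + logw[None, :] - person_ll[:, None])
        for j, p in enumerate(items):
            C = n_cats[j]
            r_gk = np.stack(
                [post[values[:, j] == k].sum(axis=0) for k in range(C)], axis=1
            )
            s, d = _mstep_graded_item(
                r_gk, x[:, None], np.array([p.a]), p.a * p.thresholds, ridge
            )
            a_new = max(abs(float(s[0])), 1e-4)
            p.a = a_new
            p.thresholds = np.sort(d / a_new)
    if not converged:
        warnings.warn(f"GRM fit did not converge in {it} iterations", stacklevel=2)

    fit = GRMFit(
        items=items,
        loglik=ll_path[-1],
        n_persons=n,
        converged=converged,
        n_iter=it,
    )
    if compute_se:
        _attach_ses(fit, values, n_quad)
    for p in fit.items:
        if p.a < 0.25 or (np.isfinite(p.a_se) and p.a_se > 1.0):
            p.flagged = "weak_discrimination"
    return fit


def _attach_ses(fit: GRMFit, values: np.ndarray, n_quad: int) -> None:
    """SEs from the empirical information (outer product of person scores)."""
    x, w = norm_grid(n_quad)
    logw = np.log(w)

    packs = [pack_graded(p.a, p.thresholds) for p in fit.items]
    sizes = [len(v) for v in packs]
    theta0 = np.concatenate(packs)

    def person_ll(vec):
        pos = 0
        tmp = []
        for p, size in zip(fit.items, sizes):
            a, th = unpack_graded(vec[pos : pos + size])
            tmp.append(GradedItemParams(p.item_id, a, th))
            pos += size
        LL = _grid_loglik(values, tmp, x)
        return logsumexp(LL + logw[None, :], axis=1)

    h = 1e-5
    scores = np.empty((values.shape[0], len(theta0)))
    for k in range(len(theta0)):
        up, dn = theta0.copy(), theta0.copy()
        up[k] += h
        dn[k] -= h
        scores[:, k] = (person_ll(up) - person_ll(dn)) / (2 * h)
    info = scores.T @ scores
    try:
        cov_pack = np.linalg.inv(info + 1e-10 * np.eye(len(theta0)))
    except np.linalg.LinAlgError:
        cov_pack = np.full((len(theta0), len(theta0)), np.nan)
    # delta method back to (a, b1..bK)
    pos = 0
    for p, size in zip(fit.items, sizes):
        sub = cov_pack[pos : pos + size, pos : pos + size]
        vec = theta0[pos : pos + size]
        Jac = np.zeros((size, size))
        Jac[0, 0] = np.exp(vec[0])  # da/dloga
        for krow in range(1, size):
            Jac[krow, 1] = 1.0
            for kc in range(2, krow + 1):
                Jac[krow, kc] = np.exp(vec[kc])
        cov_nat = Jac @ sub @ Jac.T
        ses = np.sqrt(np.clip(np.diag(cov_nat), 0.0, None))
        p.a_se = float(ses[0])
        p.thresholds_se = ses[1:]
        pos += size


def eap_scores(items: list, sev: SeverityMatrix, n_quad: int = 61) -> PersonScoreTable:
    """EAP severity scores under a standard-normal prior.

    Persons with no administered rating fall back to the prior (mean 0,
    SD 1) and are flagged.
    """
    x, w = norm_grid(n_quad)
    values = _recode(sev, items)
    LL = _grid_loglik(values, items, x)
    logpost = LL + np.log(w)[None, :]
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    mean = post @ x
    sd = np.sqrt(np.clip(post @ x**2 - mean**2, 1e-12, None))
    no_obs = ~(~np.isnan(values)).any(axis=1)
    mean[no_obs] = 0.0
    sd[no_obs] = 1.0
    flags = {
        pid: "no_administered_ratings"
        for pid, miss in zip(sev.person_ids, no_obs)
        if miss
    }
    return PersonScoreTable(list(sev.person_ids), mean, sd, flags)
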