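"""Independent brute-force oracles used by the tests.

Everything here integrates on dense trapezoid grids or enumerates directly,
sharing no code path with the package's quadrature/EM/MCMC machinery.
"""

from __future__ import annotations

import numpy as np


def _phi(t):
    return np.exp(-0.5 * t**2) / np.sqrt(2.0 * np.pi)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def uni_marginal_loglik(Y, a, c, grid_n=10001, lim=10.0):
    """Unidimensional binary marginal log-likelihood on a dense 1-D grid."""
    t = np.linspace(-lim, lim, grid_n)
    total = 0.0
    for row in Y:
        lik = np.ones_like(t)
        for j, y in enumerate(row):
            if np.isnan(y):
                continue
            p = _sigmoid(a[j] * t + c[j])
            lik = lik * (p if y == 1 else 1.0 - p)
        total += np.log(np.trapezoid(lik * _phi(t), t))
    return total


def bifactor_marginal_loglik(Y, a0, asp, c, grid_n=2001, lim=8.0):
    """One-domain bifactor (2 latent dims) marginal log-lik on a 2-D grid."""
    t0 = np.linspace(-lim, lim, grid_n)
    t1 = np.linspace(-lim, lim, grid_n)
    T0, T1 = np.meshgrid(t0, t1, indexing="ij")
    W = _phi(T0) * _phi(T1)
    total = 0.0
    for row in Y:
        lik = np.ones_like(T0)
        for j, y in enumerate(row):
            if np.isnan(y):
                continue
            p = _sigmoid(a0[j] * T0 + asp[j] * T1 + c[j])
            lik = lik * (p if y == 1 else 1.0 - p)
        total += np.log(
            np.trapezoid(np.trapezoid(lik * W, t1, axis=1), t0)
        )
    return total


def correlated2_marginal_loglik(Y, a, c, item_dim, rho, grid_n=2001, lim=8.0):
    """Two correlated factors, each item loading on one of them."""
    t0 = np.linspace(-lim, lim, grid_n)
    t1 = np.linspace(-lim, lim, grid_n)
    T0, T1 = np.meshgrid(t0, t1, indexing="ij")
    det = 1.0 - rho**2
    W = np.exp(-(T0**2 - 2 * rho * T0 * T1 + T1**2) / (2 * det)) / (
        2 * np.pi * np.sqrt(det)
    )
    total = 0.0
    for row in Y:
        lik = np.ones_like(T0)
        for j, y in enumerate(row):
            if np.isnan(y):
                continue
            t = T0 if item_dim[j] == 0 else T1
            p = _sigmoid(a[j] * t + c[j])
            lik = lik * (p if y == 1 else 1.0 - p)
        total += np.log(np.trapezoid(np.trapezoid(lik * W, t1, axis=1), t0))
    return total


def grm_marginal_loglik(Y, a, thresholds, grid_n=10001, lim=10.0):
    """Graded response marginal log-likelihood on a dense 1-D grid."""
    t = np.linspace(-lim, lim, grid_n)
    total = 0.0
    for row in Y:
        lik = np.ones_like(t)
        for j, y in enumerate(row):
            if np.isnan(y):
                continue
            b = thresholds[j]
            cum = [np.ones_like(t)]
            cum += [_sigmoid(a[j] * (t - bk)) for bk in b]
            cum.append(np.zeros_like(t))
            lik = lik * (cum[int(y)] - cum[int(y) + 1])
        total += np.log(np.trapezoid(lik * _phi(t), t))
    return total


def grm_eap(Y, a, thresholds, grid_n=10001, lim=10.0):
    """EAP means/SDs under the graded model on a dense grid."""
    t = np.linspace(-lim, lim, grid_n)
    means, sds = [], []
    for row in Y:
        lik = _phi(t).copy()
        for j, y in enumerate(row):
            if np.isnan(y):
                continue
            b = thresholds[j]
            cum = [np.ones_like(t)]
            cum += [_sigmoid(a[j] * (t - bk)) for bk in b]
            cum.append(np.zeros_like(t))
            lik = lik * (cum[int(y)] - cum[int(y) + 1])
        lik = lik / np.trapezoid(lik, t)
        m = np.trapezoid(lik * t, t)
        means.append(m)
        sds.append(np.sqrt(np.trapezoid(lik * (t - m) ** 2, t)))
    return np.array(means), np.array(sds)


def binary_eap(Y, a, c, grid_n=10001, lim=10.0):
    """EAP means under the unidimensional binary model on a dense grid."""
    t = np.linspace(-lim, lim, grid_n)
    means = []
    for row in Y:
        lik = _phi(t).copy()
        for j, y in enumerate(row):
            if np.isnan(y):
                continue
            p = _sigmoid(a[j] * t + c[j])
            lik = lik * (p if y == 1 else 1.0 - p)
        lik = lik / np.trapezoid(lik, t)
        means.append(np.trapezoid(lik * t, t))
    return np.array(means)


def testlet_posterior_theta(Y, a, b, sigma, grid_n=401, lim=6.0):
    """Posterior mean of theta per person for a one-domain testlet model
    with item parameters and sigma fixed; dense 2-D (theta, gamma) grid."""
    tg = np.linspace(-lim, lim, grid_n)
    gg = np.linspace(-lim, lim, grid_n)
    T, G = np.meshgrid(tg, gg, indexing="ij")
    prior = _phi(T) * np.exp(-0.5 * G**2 / sigma**2)
    means = []
    for row in Y:
        ll = np.zeros_like(T)
        for j, y in enumerate(row):
            if np.isnan(y):
                continue
            p = _sigmoid(a[j] * (T - b[j] - G))
            ll = ll + (np.log(p) if y == 1 else np.log(1.0 - p))
        post = np.exp(ll) * prior
        post = post / post.sum()
        means.append(float((post * T).sum()))
    return np.array(means)
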