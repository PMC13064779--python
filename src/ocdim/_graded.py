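"""Cumulative-logit (graded response) primitives shared by estimators.

An ordinal item with C categories is parameterized by one discrimination a and
C-1 ordered thresholds b_1 <= ... <= b_{C-1} on the latent metric:

    P(Y >= k | theta) = logistic(a * (theta - b_k)),   k = 1..C-1

with P(Y >= 0) = 1 and P(Y >= C) = 0; category probabilities are successive
differences of the cumulative curve. Multidimensional variants use a linear
predictor eta in place of a*theta, with intercepts d_k = a*b_k.
"""

from __future__ import annotations

import numpy as np

from ._quad import sigmoid


def category_probs(a: float, thresholds: np.ndarray, theta) -> np.ndarray:
    """P(Y = k) for k = 0..C-1 at each theta; last axis indexes categories."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be non-decreasing")
    theta = np.asarray(theta, dtype=float)
    cum = sigmoid(a * (theta[..., None] - thresholds))  # P(Y>=1..C-1)
    upper = np.concatenate(
        [np.ones(theta.shape + (1,)), cum, np.zeros(theta.shape + (1,))], axis=-1
    )
    return upper[..., :-1] - upper[..., 1:]


def category_logprobs_eta(eta: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Log category probabilities given linear predictor eta and intercepts d.

    ``eta`` any shape, ``d`` increasing (C-1,). Returns shape eta.shape + (C,)
    computed stably (probabilities floored at ~1e-300 before the log).
    """
    d = np.asarray(d, dtype=float)
    eta = np.asarray(eta, dtype=float)
    cum = sigmoid(eta[..., None] - d)
    upper = np.concatenate(
        [np.ones(eta.shape + (1,)), cum, np.zeros(eta.shape + (1,))], axis=-1
    )
    probs = np.clip(upper[..., :-1] - upper[..., 1:], 1e-300, None)
    return np.log(probs)


def collapse_categories(col: np.ndarray) -> tuple[np.ndarray, dict]:
    """Remap an ordinal column so observed categories are contiguous 0..C'-1.

    Unobserved categories are merged downward (an empty level k maps every
    higher observed level down by one). Returns the recoded column (NaN kept)
    and the old->new mapping for the log.
    """
    col = np.asarray(col, dtype=float)
    observed = np.unique(col[~np.isnan(col)]).astype(int)
    mapping = {int(old): rank for rank, old in enumerate(np.sort(observed))}
    out = col.copy()
    for old, new in mapping.items():
        out[col == old] = new
    return out, mapping


def pack_graded(a: float, thresholds: np.ndarray) -> np.ndarray:
    """(a, b1..bK) -> unconstrained vector (log a, b1, log increments)."""
    thresholds = np.asarray(thresholds, dtype=float)
    inc = np.diff(thresholds)
    return np.concatenate(
        [[np.log(a)], [thresholds[0]], np.log(np.clip(inc, 1e-6, None))]
    )


def unpack_graded(vec: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(vec[0]))
    thresholds = vec[1] + np.concatenate([[0.0], np.cumsum(np.exp(vec[2:]))])
    return a, thresholds
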