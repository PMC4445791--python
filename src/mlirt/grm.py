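"""Graded Response Model (GRM) probabilities and likelihood.

The GRM is the measurement half of the multilevel IRT model: for an item
with discrimination ``a`` and ordered thresholds ``kappa_1 < ... < kappa_{C-1}``,
the probability of responding in category ``c`` or above is

    P(Y >= c | theta) = F(a * (theta - kappa_c)),

where ``F`` is either the logistic or the standard-normal CDF and ``theta``
is the latent health score (higher = worse health).  Category probabilities
follow by adjacent differencing of the cumulative curves.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit, ndtr

__all__ = ["cumulative_prob", "category_probs", "loglik", "LINKS"]

LINKS = ("logit", "probit")

# floor before taking logs so a single impossible cell cannot poison a
# deviance trace with -inf
_PROB_FLOOR = 1e-300


def _link_cdf(x: np.ndarray, link: str) -> np.ndarray:
    if link == "logit":
        return expit(x)
    if link == "probit":
        return ndtr(x)
    raise ValueError(f"unknown link {link!r}; expected one of {LINKS}")


def cumulative_prob(a: float, kappa_c: float, theta, link: str = "probit"):
    """P(Y >= c | theta) = F(a * (theta - kappa_c)).

    Strictly increasing in ``theta`` and equal to 0.5 at ``theta == kappa_c``
    for both links.  ``theta`` may be a scalar or array.
    """
    if np.any(np.asarray(a) <= 0):
        raise ValueError("discrimination a must be > 0")
    theta = np.asarray(theta, dtype=float)
    return _link_cdf(a * (theta - kappa_c), link)


def _check_item(a: float, kappa: np.ndarray) -> np.ndarray:
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    if np.any(np.asarray(a) <= 0):
        raise ValueError("discrimination a must be > 0")
    if kappa.ndim != 1 or np.any(np.diff(kappa) <= 0):
        raise ValueError("thresholds must be a strictly increasing vector")
    return kappa


def category_probs(a: float, kappa, theta, link: str = "probit") -> np.ndarray:
    """Probability of each of the C = len(kappa)+1 ordered categories.

    p_c = P(Y >= c) - P(Y >= c+1) with P(Y >= 0) = 1 and P(Y >= C) = 0.
    Returns an array whose last axis has length C; rows sum to 1.
    """
    kappa = _check_item(a, kappa)
    theta = np.asarray(theta, dtype=float)
    # cumulative curves for c = 1..C-1, stacked on the last axis
    cum = _link_cdf(a * (theta[..., None] - kappa), link)
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    cum_full = np.concatenate([ones, cum, zeros], axis=-1)
    p = -np.diff(cum_full, axis=-1)
    return np.clip(p, 0.0, 1.0)


def loglik(values: np.ndarray, mask: np.ndarray, a: np.ndarray,
           kappa: np.ndarray, theta: np.ndarray, link: str = "probit") -> float:
    """Observed-data log-likelihood of an ordinal response matrix.

    Parameters
    ----------
    values : (n, K) int array of category codes 0..C-1 (anything under mask).
    mask : (n, K) bool array, True where the response is missing; missing
        cells contribute nothing.
    a : (K,) discriminations; kappa : (K, C-1) thresholds, rows increasing.
    theta : (n,) latent scores.
    """
    values = np.asarray(values)
    mask = np.asarray(mask, dtype=bool)
    a = np.asarray(a, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n, K = values.shape
    if a.shape != (K,) or kappa.shape[0] != K or theta.shape != (n,):
        raise ValueError("inconsistent dimensions")
    total = 0.0
    hit_zero = False
    for k in range(K):
        obs = ~mask[:, k]
        if not obs.any():
            continue
        p = category_probs(a[k], kappa[k], theta[obs], link)
        pc = p[np.arange(obs.sum()), values[obs, k]]
        if np.any(pc <= 0):
            hit_zero = True
        total += float(np.sum(np.log(np.maximum(pc, _PROB_FLOOR))))
    if hit_zero:
        warnings.warn("zero-probability response cell encountered; "
                      "log-likelihood floored", RuntimeWarning, stacklevel=2)
    return total
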