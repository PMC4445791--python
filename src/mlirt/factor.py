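"""Polychoric correlations and ordinary/bifactor factor analysis of ordinal items.

Three primitives used by the IRT assumption diagnostics:

* two-step maximum-likelihood polychoric correlations (thresholds from the
  univariate margins, the latent correlation by ML on the two-way table);
* minres (minimum-residual / ULS) factor extraction, the standard choice for
  factoring a polychoric matrix that need not be positive definite;
* an orthogonal gradient-projection rotation with the bi-quartimin
  criterion, which rotates a 1+G factor solution toward a bifactor pattern
  (one general factor, orthogonal group factors).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtri

__all__ = ["polychoric_corr", "polychoric_matrix", "minres_factor",
           "rotate_bifactor", "smooth_corr"]


# ---------------------------------------------------------------------------
# polychoric


def _thresholds_from_margin(counts: np.ndarray) -> np.ndarray:
    """Normal-quantile thresholds from marginal category proportions."""
    p = counts / counts.sum()
    cum = np.cumsum(p)[:-1]
    cum = np.clip(cum, 1e-10, 1 - 1e-10)
    return ndtri(cum)


def _bvn_rectangles(rho: float, tx: np.ndarray, ty: np.ndarray) -> np.ndarray:
    """Cell probabilities of a discretized standard bivariate normal."""
    gx = np.concatenate([[-np.inf], tx, [np.inf]])
    gy = np.concatenate([[-np.inf], ty, [np.inf]])
    # CDF at the full corner grid, then 2-D differencing
    xs, ys = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    finite = np.isfinite(pts).all(axis=1)
    cdf = np.zeros(len(pts))
    upper_x = np.isinf(pts[:, 0]) & (pts[:, 0] > 0)
    upper_y = np.isinf(pts[:, 1]) & (pts[:, 1] > 0)
    if finite.any():
        mvn = stats.multivariate_normal(mean=[0.0, 0.0],
                                        cov=[[1.0, rho], [rho, 1.0]],
                                        allow_singular=True)
        cdf[finite] = mvn.cdf(pts[finite])
    # corners with a +inf coordinate reduce to the univariate (or unit) CDF
    only_x = upper_y & ~np.isinf(pts[:, 0])
    only_y = upper_x & ~np.isinf(pts[:, 1])
    cdf[only_x] = stats.norm.cdf(pts[only_x, 0])
    cdf[only_y] = stats.norm.cdf(pts[only_y, 1])
    cdf[upper_x & upper_y] = 1.0
    C = cdf.reshape(len(gx), len(gy))
    cells = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
    return np.clip(cells, 1e-12, 1.0)


def polychoric_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML polychoric correlation of two ordinal variables.

    Missing entries (negative codes or NaN) are dropped pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (x >= 0) & (y >= 0)
    x, y = x[ok].astype(int), y[ok].astype(int)
    cx = np.bincount(x)
    cy = np.bincount(y)
    if (cx > 0).sum() < 2 or (cy > 0).sum() < 2:
        raise ValueError("variable with a single observed category")
    tx = _thresholds_from_margin(cx)
    ty = _thresholds_from_margin(cy)
    table = np.zeros((len(cx), len(cy)))
    np.add.at(table, (x, y), 1.0)

    def negloglik(rho):
        return -float(np.sum(table * np.log(_bvn_rectangles(rho, tx, ty))))

    res = optimize.minimize_scalar(negloglik, bounds=(-0.999, 0.999),
                                   method="bounded",
                                   options={"xatol": 1e-5})
    return float(res.x)


def polychoric_matrix(values: np.ndarray, mask: np.ndarray | None = None):
    """Pairwise polychoric correlation matrix of an ordinal response matrix.

    Items with a single observed category are excluded with a warning.
    Returns ``(R, kept_column_indices)``.
    """
    values = np.asarray(values, dtype=float)
    if mask is not None:
        values = np.where(np.asarray(mask, bool), np.nan, values)
    K = values.shape[1]
    kept = []
    for k in range(K):
        col = values[:, k]
        obs = col[np.isfinite(col)]
        if np.unique(obs).size < 2:
            warnings.warn(f"item column {k} has a single observed category; "
                          "excluded from polychoric matrix", stacklevel=2)
        else:
            kept.append(k)
    if len(kept) < 2:
        raise ValueError("need >= 2 items with >= 2 observed categories")
    m = len(kept)
    R = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            r = polychoric_corr(values[:, kept[i]], values[:, kept[j]])
            R[i, j] = R[j, i] = r
    return R, kept


def smooth_corr(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Nearest-eigenvalue smoothing so the matrix is positive semi-definite."""
    w, V = np.linalg.eigh((R + R.T) / 2)
    if w.min() >= eps:
        return R
    w = np.clip(w, eps, None)
    S = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


# ---------------------------------------------------------------------------
# minres factor extraction


def minres_factor(R: np.ndarray, n_factors: int = 1,
                  method: str = "minres") -> np.ndarray:
    """Minimum-residual (ULS) factor loadings of a correlation matrix.

    Optimizes the uniquenesses; given uniquenesses the loadings follow from
    the leading eigenpairs of the reduced matrix.  ``method='ml'`` swaps in
    the normal-theory ML discrepancy.  Loadings with a Heywood communality
    are clipped to 1 with a warning.
    """
    R = smooth_corr(np.asarray(R, dtype=float))
    p = R.shape[0]
    if n_factors < 1 or n_factors >= p:
        raise ValueError("need 1 <= n_factors < n_items")

    def loadings_given_psi(psi):
        Rr = R - np.diag(psi)
        w, V = np.linalg.eigh(Rr)
        idx = np.argsort(w)[::-1][:n_factors]
        lam = V[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
        return lam

    def objective(logit_psi):
        psi = 1e-4 + (1 - 2e-4) / (1 + np.exp(-logit_psi))
        lam = loadings_given_psi(psi)
        resid = R - lam @ lam.T - np.diag(psi)
        if method == "ml":
            S = lam @ lam.T + np.diag(psi)
            sign, logdet = np.linalg.slogdet(S)
            if sign <= 0:
                return 1e10
            return logdet + np.trace(np.linalg.solve(S, R)) - np.log(
                max(np.linalg.det(R), 1e-300)) - p
        iu = np.triu_indices(p, 1)
        return float(np.sum(resid[iu] ** 2))

    start = np.zeros(p)  # psi ~ 0.5
    res = optimize.minimize(objective, start, method="L-BFGS-B")
    psi = 1e-4 + (1 - 2e-4) / (1 + np.exp(-res.x))
    lam = loadings_given_psi(psi)
    comm = np.sum(lam ** 2, axis=1)
    if np.any(comm > 1.0):
        warnings.warn("Heywood case: communality > 1 clipped", stacklevel=2)
        lam = lam * np.minimum(1.0, 1.0 / np.sqrt(comm))[:, None]
    # orient each factor so its largest loading is positive
    for j in range(lam.shape[1]):
        if lam[np.argmax(np.abs(lam[:, j])), j] < 0:
            lam[:, j] = -lam[:, j]
    return lam


# ---------------------------------------------------------------------------
# orthogonal gradient-projection bifactor rotation


def _biquartimin_criterion(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Quartimin criterion on the group-factor block (columns 2..), with a
    zero gradient for the general (first) column."""
    L2 = L[:, 1:]
    sq = L2 ** 2
    N = np.ones((sq.shape[1], sq.shape[1])) - np.eye(sq.shape[1])
    f = float(np.sum(sq * (sq @ N))) / 4.0
    G = np.zeros_like(L)
    G[:, 1:] = L2 * (sq @ N)
    return f, G


def rotate_bifactor(A: np.ndarray, max_iter: int = 5000,
                    tol: float = 1e-5) -> np.ndarray:
    """Orthogonal GPA rotation of loadings ``A`` (p x (1+G)) to a bifactor
    pattern using the bi-quartimin criterion.

    Raises ``RuntimeError`` (with the iteration trace attached) if the
    gradient projection does not converge.
    """
    A = np.asarray(A, dtype=float)
    T = np.eye(A.shape[1])
    alpha = 1.0
    L = A @ T
    f, G = _biquartimin_criterion(L)
    trace = [f]
    for _ in range(max_iter):
        Gp = A.T @ G
        M = T.T @ Gp
        S = (M + M.T) / 2
        Gproj = Gp - T @ S
        s = np.linalg.norm(Gproj)
        if s < tol:
            break
        alpha *= 2
        for _ in range(60):
            X = T - alpha * Gproj
            U, _, Vt = np.linalg.svd(X)
            Tt = U @ Vt
            Lt = A @ Tt
            ft, Gt = _biquartimin_criterion(Lt)
            if ft < f - 0.5 * s**2 * alpha:
                break
            alpha /= 2
        T, f, G = Tt, ft, Gt
        trace.append(f)
    else:
        err = RuntimeError("bifactor rotation did not converge")
        err.trace = trace  # type: ignore[attr-defined]
        raise err
    L = A @ T
    # orient: general factor positive, group factors positive-dominant
    for j in range(L.shape[1]):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] = -L[:, j]
    # put the column with the broadest support first (general factor)
    strength = (np.abs(L) > 0.2).sum(axis=0) + np.abs(L).sum(axis=0) / L.shape[0]
    order = np.argsort(-strength)
    general = order[0]
    cols = [general] + [j for j in range(L.shape[1]) if j != general]
    return L[:, cols]
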