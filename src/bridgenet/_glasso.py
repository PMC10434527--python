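"""Graphical-lasso solver: Friedman block coordinate descent, numba-compiled.

Solves, for a correlation (or covariance) matrix S and penalty ``lam``,

    maximize_K  log det K - tr(S K) - lam * sum_{i != j} |K_ij|

over symmetric positive-definite K.  The diagonal is unpenalized, so at
``lam = 0`` the solution is exactly ``inv(S)`` and at
``lam >= max_{i != j} |S_ij|`` the solution is diagonal.

The outer loop cycles over columns of the working covariance W, solving the
dual lasso subproblem for each column by coordinate descent; K is recovered
from the final regression coefficients.  Warm starts (passing the W from a
neighbouring penalty) make a whole descending-lambda path cost only a few
milliseconds for p ~ 20.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _lasso_cd(V, u, lam, beta, tol, max_iter):
    # min_beta 0.5 beta'V beta - u'beta + lam ||beta||_1, cyclic soft-threshold
    p = V.shape[0]
    for _ in range(max_iter):
        dmax = 0.0
        for j in range(p):
            r = u[j]
            for k in range(p):
                if k != j:
                    r -= V[j, k] * beta[k]
            if r > lam:
                bj = (r - lam) / V[j, j]
            elif r < -lam:
                bj = (r + lam) / V[j, j]
            else:
                bj = 0.0
            d = abs(bj - beta[j])
            if d > dmax:
                dmax = d
            beta[j] = bj
        if dmax < tol:
            break
    return beta


@njit(cache=True)
def _glasso_cd(S, lam, W, tol, max_iter):
    p = S.shape[0]
    B = np.zeros((p, p))
    for _ in range(max_iter):
        dmax = 0.0
        for j in range(p):
            V = np.empty((p - 1, p - 1))
            u = np.empty(p - 1)
            beta = np.empty(p - 1)
            r = 0
            for a in range(p):
                if a == j:
                    continue
                u[r] = S[a, j]
                beta[r] = B[a, j]
                c = 0
                for b in range(p):
                    if b == j:
                        continue
                    V[r, c] = W[a, b]
                    c += 1
                r += 1
            beta = _lasso_cd(V, u, lam, beta, tol * 0.1, max_iter)
            w12 = V @ beta
            r = 0
            for a in range(p):
                if a == j:
                    continue
                d = abs(W[a, j] - w12[r])
                if d > dmax:
                    dmax = d
                W[a, j] = w12[r]
                W[j, a] = w12[r]
                B[a, j] = beta[r]
                r += 1
        if dmax < tol:
            break
    # K from the column regressions: K_jj = 1/(W_jj - w12'beta), K_.j = -beta K_jj
    K = np.empty((p, p))
    for j in range(p):
        s = 0.0
        for a in range(p):
            if a != j:
                s += W[a, j] * B[a, j]
        kjj = 1.0 / (W[j, j] - s)
        K[j, j] = kjj
        for a in range(p):
            if a != j:
                K[a, j] = -B[a, j] * kjj
    for a in range(p):
        for b in range(a + 1, p):
            m = 0.5 * (K[a, b] + K[b, a])
            K[a, b] = m
            K[b, a] = m
    return W, K


def glasso(
    S: np.ndarray,
    lam: float,
    W_init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the off-diagonal-penalized glasso problem.

    Parameters
    ----------
    S
        Symmetric sample correlation/covariance matrix.
    lam
        Nonnegative l1 penalty on off-diagonal precision entries.
    W_init
        Optional warm-start estimated covariance (from a nearby ``lam``).
    tol
        Convergence threshold on the max absolute change of W per sweep.
    max_iter
        Cap on outer sweeps (and inner lasso iterations).

    Returns
    -------
    (W, K)
        Estimated covariance and precision matrices.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    if W_init is None:
        W = S.copy()
    else:
        W = np.ascontiguousarray(W_init, dtype=np.float64).copy()
        np.fill_diagonal(W, np.diag(S))  # diagonal is unpenalized and fixed
    if S.shape[0] == 1:
        return S.copy(), np.array([[1.0 / S[0, 0]]])
    return _glasso_cd(S, float(lam), W, float(tol), int(max_iter))
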