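"""Graphical-LASSO solver (Friedman block coordinate descent).

Solves  max_K  logdet K - tr(S K) - lam * sum_{i != j} |K_ij|  for a
positive-definite input S by the classic block coordinate descent over the
working covariance W: each column in turn is updated by solving the
equivalent lasso subproblem with cyclic coordinate descent and
soft-thresholding, which yields exact zeros in the precision matrix.  The
diagonal is unpenalized, so diag(W) = diag(S) throughout.

The sweep converges when the largest absolute change of W in one full pass
falls below `tol` (default 1e-6).  Numba-compiled; a 10-node problem takes
well under a millisecond, which is what makes whole-pipeline bootstrap
stability analyses affordable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glasso"]


@njit(cache=True)
def _glasso_core(S, lam, W, tol, max_iter, inner_tol, inner_max_iter):
    p = S.shape[0]
    beta_all = np.zeros((p, p))  # row j: lasso coefficients for column j
    for it in range(max_iter):
        max_change = 0.0
        for j in range(p):
            # indices of the block without j
            idx = np.empty(p - 1, dtype=np.int64)
            c = 0
            for i in range(p):
                if i != j:
                    idx[c] = i
                    c += 1
            beta = beta_all[j].copy()
            # cyclic coordinate descent on
            #   0.5 b' W11 b - s12' b + lam |b|_1
            for _ in range(inner_max_iter):
                inner_change = 0.0
                for a in range(p - 1):
                    k = idx[a]
                    r = S[k, j]
                    for b in range(p - 1):
                        l = idx[b]
                        if l != k:
                            r -= W[k, l] * beta[l]
                    old = beta[k]
                    if r > lam:
                        beta[k] = (r - lam) / W[k, k]
                    elif r < -lam:
                        beta[k] = (r + lam) / W[k, k]
                    else:
                        beta[k] = 0.0
                    d = abs(beta[k] - old)
                    if d > inner_change:
                        inner_change = d
                if inner_change < inner_tol:
                    break
            beta_all[j] = beta
            # w12 = W11 beta
            for a in range(p - 1):
                k = idx[a]
                w = 0.0
                for b in range(p - 1):
                    l = idx[b]
                    w += W[k, l] * beta[l]
                d = abs(W[k, j] - w)
                if d > max_change:
                    max_change = d
                W[k, j] = w
                W[j, k] = w
        if max_change < tol:
            return W, beta_all, it + 1, True
    return W, beta_all, max_iter, False


@njit(cache=True)
def _recover_precision(W, beta_all):
    p = W.shape[0]
    K = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for k in range(p):
            if k != j:
                dot += W[k, j] * beta_all[j, k]
        kjj = 1.0 / (W[j, j] - dot)
        K[j, j] = kjj
        for k in range(p):
            if k != j:
                K[k, j] = -beta_all[j, k] * kjj
    # exact symmetrization, preserving exact zeros
    for i in range(p):
        for j in range(i + 1, p):
            if K[i, j] == 0.0 or K[j, i] == 0.0:
                K[i, j] = 0.0
                K[j, i] = 0.0
            else:
                v = 0.5 * (K[i, j] + K[j, i])
                K[i, j] = v
                K[j, i] = v
    return K


def glasso(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 200,
    W_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """One penalized fit.

    Returns ``(precision, covariance, n_sweeps, converged)``; `W_init`
    allows warm starts along a penalty path.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    p = S.shape[0]
    if S.shape != (p, p):
        raise ValueError("S must be square")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    W = S.copy() if W_init is None else np.ascontiguousarray(W_init, dtype=np.float64).copy()
    np.fill_diagonal(W, np.diag(S))  # diagonal is unpenalized
    W, beta_all, n_iter, converged = _glasso_core(
        S, float(lam), W, float(tol), int(max_iter), float(tol) * 1e-2, 1000
    )
    K = _recover_precision(W, beta_all)
    return K, W, n_iter, converged
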