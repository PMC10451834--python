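"""Block coordinate-descent solver for the graphical lasso.

Solves, for a positive-definite input matrix ``S`` (here always a
correlation matrix) and penalty ``lam``::

    maximize_{Theta > 0}  log det(Theta) - tr(S Theta) - lam * sum_{i != j} |Theta_ij|

i.e. the L1 penalty is applied to off-diagonal precision entries only.
The solver is the classical column-wise block coordinate descent: each
column update is an L1-penalized quadratic program solved by cyclic
coordinate descent on the regression coefficients beta, with the working
covariance ``W`` kept in sync.  Small problem sizes (p ~ 10 nodes) are the
design target; the kernels are numba-compiled because resampling and
permutation procedures re-estimate the model tens of thousands of times.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glasso", "GlassoNonConvergence"]


class GlassoNonConvergence(RuntimeError):
    """Raised when coordinate descent fails to reach the duality-gap tolerance."""

    def __init__(self, gap: float, max_sweeps: int):
        self.gap = gap
        self.max_sweeps = max_sweeps
        super().__init__(
            f"graphical lasso did not converge in {max_sweeps} sweeps "
            f"(duality gap {gap:.3e})"
        )


@njit(cache=True)
def _dual_gap(S, Theta, lam):
    p = S.shape[0]
    gap = 0.0
    for i in range(p):
        for j in range(p):
            gap += S[i, j] * Theta[j, i]
    gap -= p
    l1 = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                l1 += abs(Theta[i, j])
    return gap + lam * l1


@njit(cache=True)
def _glasso_cd(S, lam, W, B, tol, max_sweeps):
    """Coordinate descent given warm-start working covariance W and betas B.

    Returns (Theta, gap, n_sweeps). B[:, j] holds the p-1 regression
    coefficients of column j (rows in 'all but j' order).
    """
    p = S.shape[0]
    idx = np.empty(p - 1, np.int64)
    Theta = np.empty((p, p))
    gap = np.inf
    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        max_delta = 0.0
        for col in range(p):
            k = 0
            for i in range(p):
                if i != col:
                    idx[k] = i
                    k += 1
            beta = B[:, col]
            # cyclic coordinate descent on the penalized regression
            for it in range(p - 1):
                j = idx[it]
                # r = S[j, col] - sum_{l != j} W[j, l] * beta_l  (l over idx)
                r = S[j, col]
                for lt in range(p - 1):
                    l = idx[lt]
                    if l != j:
                        r -= W[j, l] * beta[lt]
                old = beta[it]
                if r > lam:
                    new = (r - lam) / W[j, j]
                elif r < -lam:
                    new = (r + lam) / W[j, j]
                else:
                    new = 0.0
                beta[it] = new
                d = abs(new - old)
                if d > max_delta:
                    max_delta = d
            # sync working covariance column: w12 = W11 beta
            for it in range(p - 1):
                i = idx[it]
                v = 0.0
                for lt in range(p - 1):
                    v += W[i, idx[lt]] * beta[lt]
                W[i, col] = v
                W[col, i] = v
        # recover Theta and test the duality gap every sweep
        for col in range(p):
            k = 0
            dot = 0.0
            for i in range(p):
                if i != col:
                    dot += W[i, col] * B[k, col]
                    k += 1
            theta_cc = 1.0 / (W[col, col] - dot)
            Theta[col, col] = theta_cc
            k = 0
            for i in range(p):
                if i != col:
                    Theta[i, col] = -B[k, col] * theta_cc
                    k += 1
        # symmetrize (column solutions agree only at convergence)
        for i in range(p):
            for j in range(i + 1, p):
                v = 0.5 * (Theta[i, j] + Theta[j, i])
                Theta[i, j] = v
                Theta[j, i] = v
        gap = _dual_gap(S, Theta, lam)
        if abs(gap) < tol:
            break
        if max_delta < 1e-12 and sweep > 0:
            break
    return Theta, gap, sweeps


@njit(cache=True)
def _ebic_path(S, path, n, gamma, tol, max_sweeps, zero_tol):
    """Warm-started descending-penalty path with inline EBIC selection.

    Returns (best_theta, best_lam, best_ebic, worst_gap).  Ties in EBIC
    keep the earlier (larger) penalty, i.e. the sparser model.
    """
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p - 1, p))
    logn = np.log(n)
    logp = np.log(p)
    best_crit = np.inf
    best_lam = 0.0
    best_theta = np.empty((p, p))
    worst_gap = 0.0
    for k in range(path.shape[0]):
        lam = path[k]
        theta, gap, _ = _glasso_cd(S, lam, W, B, tol, max_sweeps)
        if abs(gap) > worst_gap:
            worst_gap = abs(gap)
        E = 0
        tr = 0.0
        for i in range(p):
            for j in range(p):
                if i != j and abs(theta[i, j]) < zero_tol:
                    theta[i, j] = 0.0
                tr += S[i, j] * theta[j, i]
                if j > i and theta[i, j] != 0.0:
                    E += 1
        L = np.linalg.cholesky(theta)
        logdet = 0.0
        for i in range(p):
            logdet += 2.0 * np.log(L[i, i])
        ll = 0.5 * n * (logdet - tr)
        crit = -2.0 * ll + E * logn + 4.0 * E * gamma * logp
        if crit < best_crit - 1e-12:
            best_crit = crit
            best_lam = lam
            best_theta = theta.copy()
    return best_theta, best_lam, best_crit, worst_gap


def glasso(
    S: np.ndarray,
    lam: float,
    *,
    tol: float = 1e-6,
    max_sweeps: int = 500,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
    zero_tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimate a sparse precision matrix by graphical lasso.

    Parameters
    ----------
    S
        Symmetric positive-definite covariance/correlation matrix.
    lam
        Nonnegative L1 penalty on off-diagonal precision entries.
    warm
        Optional ``(W, B)`` warm start from a previous (larger) penalty.
    zero_tol
        Off-diagonal entries smaller than this in magnitude are snapped
        to exact zero so edge counts are well defined.

    Returns
    -------
    Theta, W, B
        Precision estimate, working covariance and regression coefficients
        (the latter two reusable as a warm start at the next penalty).
    """
    S = np.asarray(S, dtype=np.float64)
    p = S.shape[0]
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if lam == 0.0:
        Theta = np.linalg.inv(S)
        Theta = 0.5 * (Theta + Theta.T)
        W = S.copy()
        B = _betas_from_precision(Theta)
        return Theta, W, B
    if warm is not None:
        W = warm[0].copy()
        B = warm[1].copy()
        np.fill_diagonal(W, np.diag(S))
    else:
        W = S.copy()
        B = np.zeros((p - 1, p))
    Theta, gap, _ = _glasso_cd(S, float(lam), W, B, float(tol), int(max_sweeps))
    if not np.isfinite(gap) or abs(gap) >= tol:
        raise GlassoNonConvergence(gap, max_sweeps)
    off = ~np.eye(p, dtype=bool)
    small = off & (np.abs(Theta) < zero_tol)
    Theta[small] = 0.0
    return Theta, W, B


def _betas_from_precision(Theta: np.ndarray) -> np.ndarray:
    p = Theta.shape[0]
    B = np.zeros((p - 1, p))
    for col in range(p):
        others = [i for i in range(p) if i != col]
        B[:, col] = -Theta[others, col] / Theta[col, col]
    return B
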