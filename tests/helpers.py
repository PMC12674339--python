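"""Independent oracles used across the test suite.

These deliberately re-derive quantities by routes different from the
package implementation: Wright's recursion for relationships, dense-V
log-likelihoods for REML, and the blockwise joint-distribution H.
"""
from __future__ import annotations

import sys
from functools import lru_cache

import numpy as np

sys.setrecursionlimit(100_000)


def wright_a(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Additive relationship matrix by memoized Wright recursion.

    Independent of the package's vectorized tabular construction; animals
    must be coded topologically with -1 for unknown parents.
    """
    n = len(sire)

    @lru_cache(maxsize=None)
    def a(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return 1.0 + 0.5 * a(int(sire[i]), int(dam[i]))
        if j > i:
            i, j = j, i
        return 0.5 * (a(j, int(sire[i])) + a(j, int(dam[i])))

    A = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            A[i, j] = A[j, i] = a(i, j)
    a.cache_clear()
    return A


def blockwise_h(A: np.ndarray, Gstar: np.ndarray, geno: np.ndarray) -> np.ndarray:
    """Joint-distribution H built block by block (dense oracle).

    H11 = A11 + A12 A22^-1 (G* - A22) A22^-1 A21, H12 = A12 A22^-1 G*,
    H22 = G*.
    """
    n = A.shape[0]
    rest = np.setdiff1d(np.arange(n), geno)
    A22 = A[np.ix_(geno, geno)]
    A22i = np.linalg.inv(A22)
    A12 = A[np.ix_(rest, geno)]
    H = np.zeros_like(A)
    H[np.ix_(rest, rest)] = (
        A[np.ix_(rest, rest)] + A12 @ A22i @ (Gstar - A22) @ A22i @ A12.T
    )
    H[np.ix_(rest, geno)] = A12 @ A22i @ Gstar
    H[np.ix_(geno, rest)] = H[np.ix_(rest, geno)].T
    H[np.ix_(geno, geno)] = Gstar
    return H


def dense_reml_loglik(
    y: np.ndarray, X: np.ndarray, K: np.ndarray, s2u: float, s2e: float
) -> float:
    """REML log-likelihood via explicit V = s2u K + s2e I (dense route)."""
    n = y.size
    V = s2u * K + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    _, ldV = np.linalg.slogdet(V)
    XVX = X.T @ Vi @ X
    _, ldX = np.linalg.slogdet(XVX)
    b = np.linalg.solve(XVX, X.T @ Vi @ y)
    return float(-0.5 * (ldV + ldX + (y - X @ b) @ Vi @ y))


def grid_reml_max(
    y: np.ndarray, X: np.ndarray, K: np.ndarray, n_grid: int = 200
) -> float:
    """Best REML log-likelihood over an n_grid x n_grid variance grid."""
    vmax = 3.0 * float(y.var())
    best = -np.inf
    for su in np.linspace(1e-4, vmax, n_grid):
        for se in np.linspace(1e-4, vmax, n_grid):
            ll = dense_reml_loglik(y, X, K, su, se)
            if ll > best:
                best = ll
    return best
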