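"""Genomic relationship matrices and the single-step H-inverse."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .genotypes import AlleleFrequencies

log = logging.getLogger(__name__)


@dataclass
class MarkerWeights:
    """Positive per-SNP weights: the diagonal of D, normalized to sum to t."""

    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if np.any(self.d <= 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("marker weights must be positive and finite")

    @classmethod
    def uniform(cls, n_snps: int) -> "MarkerWeights":
        return cls(np.ones(n_snps))

    @property
    def scale(self) -> float:
        return float(self.d.sum())

    def normalized(self) -> "MarkerWeights":
        return MarkerWeights(self.d * (self.d.size / self.d.sum()))


def g_matrix(
    Z: np.ndarray, weights: MarkerWeights, freqs: AlleleFrequencies
) -> np.ndarray:
    """Weighted genomic relationship matrix G = Z D Z' / (2 sum p q)."""
    if Z.shape[1] != weights.d.size:
        raise ValueError("weights length must equal the SNP count")
    denom = freqs.two_pq_sum
    if denom <= 0:
        raise ValueError("2*sum(p*q) is zero: all SNPs monomorphic")
    G = (Z * weights.d[np.newaxis, :]) @ Z.T / denom
    return 0.5 * (G + G.T)


def blend(G: np.ndarray, A22: np.ndarray, alpha: float) -> np.ndarray:
    """Convex combination alpha*G + (1-alpha)*A22."""
    if G.shape != A22.shape:
        raise ValueError(f"shape mismatch: G {G.shape} vs A22 {A22.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * G + (1.0 - alpha) * A22


@dataclass
class Hinverse:
    """A-inverse plus the genotyped-block correction (G*)^-1 - A22^-1."""

    ainv: sp.csr_matrix
    correction: np.ndarray
    genotyped_index: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.genotyped_index = np.asarray(self.genotyped_index, dtype=np.int64)
        g = self.genotyped_index.size
        if self.correction.shape != (g, g):
            raise ValueError("correction block shape must match genotyped set")

    @property
    def n(self) -> int:
        return self.ainv.shape[0]

    def to_dense(self) -> np.ndarray:
        M = self.ainv.toarray()
        if self.genotyped_index.size:
            M[np.ix_(self.genotyped_index, self.genotyped_index)] += self.correction
        return M

    @property
    def matrix(self) -> np.ndarray:
        return self.to_dense()


def _spd_inverse(M: np.ndarray, what: str) -> np.ndarray:
    try:
        c, low = scipy.linalg.cho_factor(M, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"{what} is singular or not positive definite; "
            "blend with alpha < 1 to regularize"
        ) from exc
    inv = scipy.linalg.cho_solve((c, low), np.eye(M.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)


def h_inverse(
    Ainv: sp.spmatrix,
    A22: np.ndarray,
    Gstar: np.ndarray,
    genotyped_index: np.ndarray,
    alpha: float = 0.95,
) -> Hinverse:
    """Assemble H^-1 = A^-1 + [0 0; 0 (G*)^-1 - A22^-1] over all animals."""
    genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
    if genotyped_index.size == 0:
        correction = np.zeros((0, 0))
    else:
        if Gstar.shape != A22.shape:
            raise ValueError("Gstar and A22 shapes differ")
        correction = _spd_inverse(Gstar, "G*") - _spd_inverse(A22, "A22")
    return Hinverse(
        ainv=sp.csr_matrix(Ainv),
        correction=correction,
        genotyped_index=genotyped_index,
        alpha=alpha,
    )
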