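"""Weighted single-step GWAS.

SNP effects are back-solved from genotyped animals' GEBVs, marker weights
are updated from the squared effects, the evaluation is repeated with the
re-weighted G, and non-overlapping windows of adjacent SNPs are scored as
percent of the additive genetic variance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

from .genotypes import AlleleFrequencies
from .kinship import MarkerWeights, blend, g_matrix, h_inverse
from .mme import MixedModelSolution, VarianceComponents, solve_mme

log = logging.getLogger(__name__)


@dataclass
class SnpEffects:
    """Per-SNP allele-substitution effects from one back-solving pass."""

    u_hat: np.ndarray
    iteration: int = 1

    def __post_init__(self) -> None:
        self.u_hat = np.asarray(self.u_hat, dtype=float)
        if not np.all(np.isfinite(self.u_hat)):
            raise ValueError("SNP effects must be finite")


@dataclass
class WindowResult:
    window_id: int
    chrom: str
    start_bp: int
    end_bp: int
    first_snp: str
    last_snp: str
    n_snps: int
    pct_var: float


@dataclass
class RegionSet:
    """Windows strictly above the variance threshold, ranked descending."""

    threshold_pct: float
    windows: list[WindowResult] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)


def backsolve_snp_effects(
    a_hat_genotyped: np.ndarray,
    Z: np.ndarray,
    weights: MarkerWeights,
    Gstar: np.ndarray,
    freqs: AlleleFrequencies,
    iteration: int = 1,
) -> SnpEffects:
    """u_hat = lambda * D Z' (G*)^-1 a_hat with lambda = 1/(2 sum p q)."""
    a = np.asarray(a_hat_genotyped, dtype=float)
    if Z.shape[0] != a.size:
        raise ValueError("GEBV vector length must equal the genotyped animal count")
    if Z.shape[1] != weights.d.size:
        raise ValueError("weights length must equal the SNP count")
    if Gstar.shape != (a.size, a.size):
        raise ValueError("Gstar shape must match the genotyped animal count")
    lam = 1.0 / freqs.two_pq_sum
    ginv_a = scipy.linalg.solve(Gstar, a, assume_a="sym", check_finite=False)
    return SnpEffects(u_hat=lam * weights.d * (Z.T @ ginv_a), iteration=iteration)


def update_weights(
    u_hat: SnpEffects,
    freqs: AlleleFrequencies,
    current: MarkerWeights,
) -> MarkerWeights:
    """Re-weight SNPs by u_hat^2 * 2pq, normalized to keep sum(d) = t.

    Raises the weight of large-effect SNPs and shrinks small ones; if all
    raw weights vanish the current weights are returned unchanged.
    """
    raw = u_hat.u_hat**2 * 2.0 * freqs.p * freqs.q
    total = raw.sum()
    if not np.isfinite(total) or total <= 0:
        log.info("all raw weights zero; keeping current marker weights")
        return MarkerWeights(current.d.copy())
    # strictly zero weights are not admissible for D; give them a tiny share
    tiny = 1e-12 * total / raw.size
    return MarkerWeights(np.maximum(raw, tiny)).normalized()


def window_variances(
    u_hat: SnpEffects,
    Z: np.ndarray,
    snp_map: pd.DataFrame,
    window_size: int,
    sigma2_a: float,
) -> list[WindowResult]:
    """Percent of additive variance per non-overlapping window of adjacent SNPs.

    For window w, a_i = Z[:, w] u_hat[w] over genotyped animals and
    pct_var = var(a_i, ddof=1) / sigma2_a * 100. The trailing window per
    chromosome may hold fewer than ``window_size`` SNPs.
    """
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    u = u_hat.u_hat
    chroms = snp_map["chrom"].to_numpy()
    pos = snp_map["pos"].to_numpy()
    ids = snp_map["id"].to_numpy()
    out: list[WindowResult] = []
    wid = 0
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx), window_size):
            block = idx[start : start + window_size]
            a_i = Z[:, block] @ u[block]
            var = float(a_i.var(ddof=1)) if a_i.size > 1 else 0.0
            out.append(WindowResult(
                window_id=wid,
                chrom=str(chrom),
                start_bp=int(pos[block[0]]),
                end_bp=int(pos[block[-1]]),
                first_snp=str(ids[block[0]]),
                last_snp=str(ids[block[-1]]),
                n_snps=len(block),
                pct_var=var / sigma2_a * 100.0,
            ))
            wid += 1
    return out


def select_regions(
    windows: list[WindowResult], threshold_pct: float
) -> RegionSet:
    """Windows explaining strictly more than ``threshold_pct`` percent."""
    chosen = [w for w in windows if w.pct_var > threshold_pct]
    chosen.sort(key=lambda w: -w.pct_var)
    return RegionSet(threshold_pct=threshold_pct, windows=chosen)


def manhattan_table(windows: list[WindowResult]) -> pd.DataFrame:
    """Plot-ready table with per-chromosome cumulative genome coordinates."""
    rows = []
    offset = 0
    last_chrom = None
    chrom_max = 0
    for w in windows:
        if w.chrom != last_chrom:
            if last_chrom is not None:
                offset += chrom_max
            last_chrom = w.chrom
            chrom_max = 0
        mid = 0.5 * (w.start_bp + w.end_bp)
        chrom_max = max(chrom_max, w.end_bp)
        rows.append({
            "chrom": w.chrom,
            "position": mid,
            "pct_var": w.pct_var,
            "cumulative_bp": offset + mid,
        })
    return pd.DataFrame(rows, columns=["chrom", "position", "pct_var", "cumulative_bp"])


@dataclass
class IterationResult:
    iteration: int
    weights: MarkerWeights           # weights used to build G this iteration
    effects: SnpEffects
    solution: MixedModelSolution
    windows: list[WindowResult]


def run_weighted_iterations(
    y: np.ndarray,
    X: np.ndarray,
    record_animals: np.ndarray,
    Ainv: sp.spmatrix,
    A22: np.ndarray,
    genotyped_index: np.ndarray,
    Z: np.ndarray,
    freqs: AlleleFrequencies,
    snp_map: pd.DataFrame,
    vc: VarianceComponents,
    *,
    alpha: float = 0.95,
    window_size: int = 30,
    n_iterations: int = 2,
    start_weights: MarkerWeights | None = None,
) -> list[IterationResult]:
    """Iteratively re-weighted ssGWAS at fixed variance components.

    Each iteration rebuilds G with the current D, re-blends, reassembles
    H^-1, re-solves the MME, back-solves SNP effects and updates D. The
    first iteration with D = I is the unweighted ssGWAS.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    weights = start_weights or MarkerWeights.uniform(Z.shape[1])
    results: list[IterationResult] = []
    for it in range(1, n_iterations + 1):
        try:
            G = g_matrix(Z, weights, freqs)
            Gstar = blend(G, A22, alpha)
            hinv = h_inverse(Ainv, A22, Gstar, genotyped_index, alpha)
            sol = solve_mme(y, X, record_animals, hinv, vc)
            a_g = sol.a_hat[genotyped_index]
            eff = backsolve_snp_effects(a_g, Z, weights, Gstar, freqs, iteration=it)
            wins = window_variances(eff, Z, snp_map, window_size, vc.sigma2_u)
        except Exception as exc:
            raise RuntimeError(f"weighted ssGWAS failed at iteration {it}") from exc
        results.append(IterationResult(
            iteration=it, weights=weights, effects=eff, solution=sol, windows=wins,
        ))
        weights = update_weights(eff, freqs, weights)
    return results
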