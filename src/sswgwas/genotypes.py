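"""Genotype quality control and the centered marker matrix.

QC order is fixed: call rate -> parent-progeny conflicts (animal removal)
-> MAF -> HWE -> LD pruning -> naive imputation. Allele frequencies are
recomputed from the surviving calls at every step.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from .pedigree import UNKNOWN, Pedigree

log = logging.getLogger(__name__)


def chrom_sort_key(label: str) -> tuple[int, int, str]:
    """Natural ordering for chromosome labels: numeric first, then lexical."""
    s = str(label)
    core = re.sub(r"^(chr|chromosome)", "", s, flags=re.IGNORECASE)
    if core.isdigit():
        return (0, int(core), "")
    return (1, 0, core)


@dataclass
class GenotypeMatrix:
    """Animals x SNPs ALT-allele dosage matrix with map and missingness mask."""

    dosages: np.ndarray          # (n_animals, n_snps) float, values in {0,1,2}
    missing_mask: np.ndarray     # bool, True where the call is missing
    snp_map: pd.DataFrame        # columns: chrom, pos, id; sorted by (chrom, pos)
    animal_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.dosages.shape != self.missing_mask.shape:
            raise ValueError("dosages and missing_mask shapes differ")
        if self.dosages.shape != (len(self.animal_ids), len(self.snp_map)):
            raise ValueError("dosage matrix shape does not match ids/map")
        self.snp_map = self.snp_map.reset_index(drop=True)
        keys = [
            (chrom_sort_key(c), int(p))
            for c, p in zip(self.snp_map["chrom"], self.snp_map["pos"])
        ]
        if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("snp_map must be sorted by (chrom, pos)")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def take_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, keep],
            self.missing_mask[:, keep],
            self.snp_map.iloc[np.atleast_1d(keep)].reset_index(drop=True),
            list(self.animal_ids),
        )

    def take_animals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.atleast_1d(keep)
        return GenotypeMatrix(
            self.dosages[keep, :],
            self.missing_mask[keep, :],
            self.snp_map.copy(),
            [self.animal_ids[i] for i in keep],
        )


@dataclass(frozen=True)
class AlleleFrequencies:
    """Per-SNP ALT allele frequency computed from non-missing calls."""

    p: np.ndarray

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def two_pq_sum(self) -> float:
        return float(2.0 * np.sum(self.p * self.q))


@dataclass
class QcReport:
    criterion: str
    removed_snps: list[str] = field(default_factory=list)
    removed_animals: list[str] = field(default_factory=list)
    n_remaining_snps: int = 0
    n_remaining_animals: int = 0

    @property
    def n_removed(self) -> int:
        return len(self.removed_snps) + len(self.removed_animals)


def _report(g: GenotypeMatrix, criterion: str, snps=(), animals=()) -> QcReport:
    rep = QcReport(
        criterion=criterion,
        removed_snps=list(snps),
        removed_animals=list(animals),
        n_remaining_snps=g.n_snps,
        n_remaining_animals=g.n_animals,
    )
    log.info(
        "QC %s: removed %d, remaining %d SNPs / %d animals",
        criterion, rep.n_removed, rep.n_remaining_snps, rep.n_remaining_animals,
    )
    return rep


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencies:
    called = ~g.missing_mask
    n_called = called.sum(axis=0)
    alt = np.where(called, g.dosages, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), np.nan)
    return AlleleFrequencies(p=p)


def filter_call_rate(
    g: GenotypeMatrix, min_rate: float
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs whose fraction of non-missing calls is below ``min_rate``."""
    rate = (~g.missing_mask).mean(axis=0)
    keep = rate >= min_rate
    out = g.take_snps(np.flatnonzero(keep))
    return out, _report(out, "call_rate", snps=g.snp_map["id"][~keep])


def filter_maf(
    g: GenotypeMatrix, maf_min: float
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs with minor allele frequency below ``maf_min``."""
    p = allele_frequencies(g).p
    maf = np.minimum(p, 1.0 - p)
    keep = ~(maf < maf_min)  # NaN (no calls) kept here; call-rate owns those
    keep &= ~np.isnan(maf) | (maf_min == 0)
    out = g.take_snps(np.flatnonzero(keep))
    return out, _report(out, "maf", snps=g.snp_map["id"][~keep])


def hwe_chi2(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """1-df chi-square of genotype counts against Hardy-Weinberg proportions.

    Returns (chi2, pvalue) per SNP; monomorphic SNPs score chi2 = 0.
    """
    called = ~g.missing_mask
    dos = np.where(called, g.dosages, -1.0)
    n0 = ((dos == 0) & called).sum(axis=0).astype(float)
    n1 = ((dos == 1) & called).sum(axis=0).astype(float)
    n2 = ((dos == 2) & called).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n1 + 2 * n2) / (2 * n)
        q = 1.0 - p
        exp = np.stack([n * q**2, n * 2 * p * q, n * p**2])
        obs = np.stack([n0, n1, n2])
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
        chi2 = terms.sum(axis=0)
    chi2 = np.where(np.isfinite(chi2), chi2, 0.0)
    pval = scipy.stats.chi2.sf(chi2, df=1)
    return chi2, pval


def filter_hwe(
    g: GenotypeMatrix, alpha: float
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs deviating from Hardy-Weinberg equilibrium at p < alpha."""
    _, pval = hwe_chi2(g)
    keep = pval >= alpha
    out = g.take_snps(np.flatnonzero(keep))
    return out, _report(out, "hwe", snps=g.snp_map["id"][~keep])


def mendel_conflict_fractions(
    g: GenotypeMatrix, ped: Pedigree
) -> tuple[np.ndarray, np.ndarray]:
    """Opposing-homozygote conflict counts per genotyped animal vs its parents.

    Returns (n_conflicts, n_checkable) arrays over g's animals; a site is
    checkable when both the animal and a genotyped parent are non-missing.
    """
    pos = {a: i for i, a in enumerate(g.animal_ids)}
    conflicts = np.zeros(g.n_animals)
    checkable = np.zeros(g.n_animals)
    called = ~g.missing_mask
    for i, a in enumerate(g.animal_ids):
        if a not in ped:
            continue
        code = ped.code(a)
        for par in (ped.sire[code], ped.dam[code]):
            if par == UNKNOWN:
                continue
            par_id = ped.ids[par]
            j = pos.get(par_id)
            if j is None:
                continue
            both = called[i] & called[j]
            checkable[i] += both.sum()
            opp = both & (
                ((g.dosages[i] == 0) & (g.dosages[j] == 2))
                | ((g.dosages[i] == 2) & (g.dosages[j] == 0))
            )
            conflicts[i] += opp.sum()
    return conflicts, checkable


def filter_mendel_conflicts(
    g: GenotypeMatrix, ped: Pedigree, max_fraction: float
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop animals whose opposing-homozygote fraction exceeds ``max_fraction``."""
    conflicts, checkable = mendel_conflict_fractions(g, ped)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(checkable > 0, conflicts / np.maximum(checkable, 1), 0.0)
    keep = frac <= max_fraction
    out = g.take_animals(np.flatnonzero(keep))
    removed = [g.animal_ids[i] for i in np.flatnonzero(~keep)]
    return out, _report(out, "mendel_conflicts", animals=removed)


def _columns_identical(x: np.ndarray, y: np.ndarray, obs: np.ndarray) -> bool:
    if obs.sum() < 2:
        return False
    return bool(np.all(x[obs] == y[obs]))


def ld_prune(
    g: GenotypeMatrix, r2_max: float, window: int = 50, step: int = 5
) -> tuple[GenotypeMatrix, QcReport]:
    """Greedy per-chromosome LD pruning in sliding windows.

    Within each window, for every pair of still-kept SNPs with squared
    Pearson dosage correlation strictly above ``r2_max`` (or exactly
    duplicated columns), the later SNP is removed. ``r2_max = 1.0``
    therefore removes only perfect duplicates.
    """
    keep = np.ones(g.n_snps, dtype=bool)
    called = ~g.missing_mask
    # mean-impute per column for the correlation computation only
    p = allele_frequencies(g).p
    filled = np.where(called, g.dosages, 2 * np.nan_to_num(p))
    chroms = g.snp_map["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx), step):
            win = idx[start : start + window]
            live = [j for j in win if keep[j]]
            for a_pos in range(len(live)):
                ja = live[a_pos]
                if not keep[ja]:
                    continue
                for jb in live[a_pos + 1 :]:
                    if not keep[jb]:
                        continue
                    xa, xb = filled[:, ja], filled[:, jb]
                    obs = called[:, ja] & called[:, jb]
                    if _columns_identical(g.dosages[:, ja], g.dosages[:, jb], obs):
                        keep[jb] = False
                        continue
                    sa, sb = xa.std(), xb.std()
                    if sa == 0 or sb == 0:
                        continue
                    r = np.corrcoef(xa, xb)[0, 1]
                    if r * r > r2_max:
                        keep[jb] = False
            if start + window >= len(idx):
                break
    out = g.take_snps(np.flatnonzero(keep))
    return out, _report(out, "ld_prune", snps=g.snp_map["id"][~keep])


def impute_naive(g: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing calls with the SNP mean dosage 2p rounded into {0,1,2}.

    Stand-in for haplotype-based imputation; never alters non-missing calls.
    """
    n_called = (~g.missing_mask).sum(axis=0)
    if np.any(n_called == 0):
        bad = g.snp_map["id"][n_called == 0].iloc[0]
        raise ValueError(
            f"SNP {bad!r} has no non-missing calls; apply the call-rate filter first"
        )
    p = allele_frequencies(g).p
    fill = np.clip(np.rint(2 * p), 0, 2)
    dos = np.where(g.missing_mask, fill[np.newaxis, :], g.dosages)
    return GenotypeMatrix(
        dos, np.zeros_like(g.missing_mask), g.snp_map.copy(), list(g.animal_ids)
    )


def center_matrix(g: GenotypeMatrix, freqs: AlleleFrequencies) -> np.ndarray:
    """Allele-frequency-centered marker matrix Z with Z_ij = x_ij - 2 p_j."""
    if g.missing_mask.any():
        raise ValueError("centering requires a complete matrix; impute first")
    return g.dosages - 2.0 * freqs.p[np.newaxis, :]


def run_qc(g: GenotypeMatrix, ped: Pedigree, cfg) -> tuple[GenotypeMatrix, list[QcReport]]:
    """Apply the full QC chain in the fixed order and impute.

    ``cfg`` is a :class:`sswgwas.data_io.RunConfig` (duck-typed: only the
    threshold fields are read).
    """
    reports: list[QcReport] = []
    g, rep = filter_call_rate(g, cfg.call_rate_min)
    reports.append(rep)
    g, rep = filter_mendel_conflicts(g, ped, cfg.mendel_conflict_max)
    reports.append(rep)
    g, rep = filter_maf(g, cfg.maf_min)
    reports.append(rep)
    g, rep = filter_hwe(g, cfg.hwe_alpha)
    reports.append(rep)
    g, rep = ld_prune(g, cfg.ld_r2_max)
    reports.append(rep)
    g = impute_naive(g)
    return g, reports
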