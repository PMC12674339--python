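"""Synthetic pedigrees, gene-dropped genotypes, QTL architectures and phenotypes.

Stands in for the study population: a multi-generation livestock pedigree
with a genotyped subset, tens of chromosomes of biallelic SNPs in founder
linkage equilibrium, a handful of large QTL over a polygenic tail, and
phenotypes with categorical period/season effects plus a covariate.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .mme import PhenotypeTable
from .pedigree import UNKNOWN, Pedigree

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    n_founders: int = 60
    n_generations: int = 8
    offspring_per_mating: int = 1
    n_sires: int = 8
    prop_genotyped: float = 0.06
    n_chromosomes: int = 5
    snps_per_chromosome: int = 600
    n_qtl: int = 1
    qtl_variance_fraction: float = 0.2
    h2: float = 0.3
    additive_variance: float = 1.0
    n_periods: int = 9
    n_seasons: int = 4
    period_effect_sd: float = 1.0
    season_effect_sd: float = 0.5
    covariate_beta: float = 0.0
    mean: float = 100.0
    missing_rate: float = 0.0
    founder_freq_range: tuple[float, float] = (0.05, 0.5)
    inter_snp_morgans: float = 0.05
    bp_spacing: int = 100_000
    # degradation planting
    n_monomorphic: int = 0
    n_low_call: int = 0
    low_call_rate: float = 0.5
    n_hwe_violations: int = 0
    n_conflict_animals: int = 0
    conflict_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_genotyped", "qtl_variance_fraction", "h2", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_founders", "n_generations", "offspring_per_mating",
                     "n_chromosomes", "snps_per_chromosome", "n_periods",
                     "n_seasons"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimulationTruth:
    true_breeding_values: np.ndarray
    qtl_positions: np.ndarray
    qtl_effects: np.ndarray
    snp_effects: np.ndarray
    realized_h2: float = float("nan")


def simulate_pedigree(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> Pedigree:
    """Discrete-generation pedigree: few sires, every dam mates once.

    Generation 0 holds the founders; each later animal has one sire drawn
    from a small random subset of the previous generation and one dam from
    the remainder. Output order is topological by construction.
    """
    rng = rng if rng is not None else cfg.rng()
    ids: list[str] = [f"G0_{i:04d}" for i in range(cfg.n_founders)]
    sire: list[int] = [UNKNOWN] * cfg.n_founders
    dam: list[int] = [UNKNOWN] * cfg.n_founders
    prev = list(range(cfg.n_founders))
    for gen in range(1, cfg.n_generations):
        n_sires = min(cfg.n_sires, max(1, len(prev) - 1))
        picks = rng.permutation(len(prev))
        sires = [prev[i] for i in picks[:n_sires]]
        dams = [prev[i] for i in picks[n_sires:]]
        if not dams:
            dams = sires[:1]
        cur: list[int] = []
        for d in dams:
            s = sires[rng.integers(len(sires))]
            for _ in range(cfg.offspring_per_mating):
                code = len(ids)
                ids.append(f"G{gen}_{code:04d}")
                sire.append(s)
                dam.append(d)
                cur.append(code)
        prev = cur
    return Pedigree(ids=tuple(ids), sire=np.array(sire), dam=np.array(dam))


def generation_of(ped: Pedigree) -> np.ndarray:
    """Generation index per animal: founders 0, else 1 + max(parent gens)."""
    gen = np.zeros(ped.n, dtype=int)
    for i in range(ped.n):
        g = -1
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                g = max(g, gen[p])
        gen[i] = g + 1
    return gen


def _transmit(hap: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    m = hap.shape[1]
    switches = np.empty(m, dtype=np.int64)
    switches[0] = rng.integers(2)
    if m > 1:
        switches[1:] = rng.random(m - 1) < r
    src = np.cumsum(switches) % 2
    return hap[src, np.arange(m)]


def gene_drop(
    ped: Pedigree,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    founder_p: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop founder alleles down the pedigree with Haldane recombination.

    Founder haplotype alleles are Bernoulli(p) with p drawn uniformly from
    ``cfg.founder_freq_range`` per SNP (or taken from ``founder_p``);
    unknown-parent haplotypes are drawn from the base population. Returns
    the all-animal dosage matrix and the drawn founder frequencies.
    """
    rng = rng if rng is not None else cfg.rng()
    m_chrom = cfg.snps_per_chromosome
    m = cfg.n_chromosomes * m_chrom
    if founder_p is None:
        lo, hi = cfg.founder_freq_range
        founder_p = rng.uniform(lo, hi, size=m)
    founder_p = np.asarray(founder_p, dtype=float)
    r = 0.5 * (1.0 - np.exp(-2.0 * cfg.inter_snp_morgans))

    dosages = np.empty((ped.n, m))
    for c in range(cfg.n_chromosomes):
        sl = slice(c * m_chrom, (c + 1) * m_chrom)
        p = founder_p[sl]
        hap = np.empty((ped.n, 2, m_chrom), dtype=np.int8)
        for i in range(ped.n):
            for slot, par in enumerate((ped.sire[i], ped.dam[i])):
                if par == UNKNOWN:
                    hap[i, slot] = rng.random(m_chrom) < p
                else:
                    hap[i, slot] = _transmit(hap[par], r, rng)
        dosages[:, sl] = hap.sum(axis=1)

    snp_map = pd.DataFrame({
        "chrom": np.repeat([str(c + 1) for c in range(cfg.n_chromosomes)], m_chrom),
        "pos": np.tile((np.arange(m_chrom) + 1) * cfg.bp_spacing, cfg.n_chromosomes),
        "id": [f"snp{c + 1}_{j + 1}" for c in range(cfg.n_chromosomes)
               for j in range(m_chrom)],
    })
    g = GenotypeMatrix(
        dosages=dosages,
        missing_mask=np.zeros_like(dosages, dtype=bool),
        snp_map=snp_map,
        animal_ids=list(ped.ids),
    )
    return g, founder_p


def _scaled_component(
    M: np.ndarray, idx: np.ndarray, raw: np.ndarray, target_var: float
) -> np.ndarray:
    """Scale effects at ``idx`` so their centered genetic values hit target_var."""
    e = np.zeros(M.shape[1])
    if idx.size == 0 or target_var <= 0:
        return e
    g = M[:, idx] @ raw
    v = g.var()
    if v <= 0:
        return e
    e[idx] = raw * np.sqrt(target_var / v)
    return e


def assign_qtl(
    g: GenotypeMatrix,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulationTruth:
    """Draw QTL positions/effects plus a polygenic tail; rescale TBV exactly.

    QTL explain ``qtl_variance_fraction`` of the additive variance, the
    remainder is spread as small Normal effects over all other SNPs; the
    final effect vector is rescaled so var(TBV) equals
    ``cfg.additive_variance`` to numerical precision.
    """
    rng = rng if rng is not None else cfg.rng()
    M = g.dosages
    m = g.n_snps
    if cfg.n_qtl > m:
        raise ValueError("n_qtl exceeds the SNP count")
    V = cfg.additive_variance
    qtl_idx = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    f = cfg.qtl_variance_fraction if cfg.n_qtl > 0 else 0.0
    eff = _scaled_component(M, qtl_idx, rng.standard_normal(cfg.n_qtl), f * V)
    poly_idx = np.setdiff1d(np.arange(m), qtl_idx)
    eff += _scaled_component(
        M, poly_idx, rng.standard_normal(poly_idx.size), (1.0 - f) * V
    )
    tbv = M @ eff
    tbv -= tbv.mean()
    v = tbv.var()
    if v > 0:
        scale = np.sqrt(V / v)
        eff *= scale
        tbv *= scale
    return SimulationTruth(
        true_breeding_values=tbv,
        qtl_positions=qtl_idx,
        qtl_effects=eff[qtl_idx],
        snp_effects=eff,
    )


def simulate_phenotypes(
    truth: SimulationTruth,
    ped: Pedigree,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """y = mean + period + season + beta*covariate + TBV + e for every animal.

    Periods follow birth generation, seasons are random; the residual SD is
    chosen so var(TBV)/(var(TBV)+s2e) equals ``cfg.h2`` and is stored in
    ``truth.realized_h2``.
    """
    rng = rng if rng is not None else cfg.rng()
    tbv = truth.true_breeding_values
    var_tbv = float(tbv.var())
    if cfg.h2 >= 1.0:
        warnings.warn("h2 = 1: zero residual variance (pipeline-test mode)")
        s2e = 0.0
        gvals = tbv
    elif cfg.h2 <= 0.0:
        s2e = cfg.additive_variance
        gvals = np.zeros_like(tbv)
        var_tbv = 0.0
    else:
        s2e = var_tbv * (1.0 - cfg.h2) / cfg.h2
        gvals = tbv
    truth.realized_h2 = var_tbv / (var_tbv + s2e) if (var_tbv + s2e) > 0 else 0.0

    gen = generation_of(ped)
    period = (gen % cfg.n_periods).astype(int)
    season = rng.integers(cfg.n_seasons, size=ped.n)
    p_eff = rng.normal(0.0, cfg.period_effect_sd, size=cfg.n_periods)
    s_eff = rng.normal(0.0, cfg.season_effect_sd, size=cfg.n_seasons)
    covar = rng.standard_normal(ped.n)
    e = rng.normal(0.0, np.sqrt(s2e), size=ped.n) if s2e > 0 else np.zeros(ped.n)
    y = cfg.mean + p_eff[period] + s_eff[season] + cfg.covariate_beta * covar + gvals + e
    return PhenotypeTable(
        animal=np.array(ped.ids, dtype=object),
        y=y,
        factors={
            "period": np.array([f"P{v + 1}" for v in period], dtype=object),
            "season": np.array([f"S{v + 1}" for v in season], dtype=object),
        },
        covariates={"afc": covar},
        trait="trait",
    )


@dataclass
class DegradationRecord:
    monomorphic_snps: list[str] = field(default_factory=list)
    low_call_snps: list[str] = field(default_factory=list)
    hwe_snps: list[str] = field(default_factory=list)
    conflict_animals: list[str] = field(default_factory=list)


def sample_genotyped(
    ped: Pedigree,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pedigree codes of the genotyped subset (drawn from late generations)."""
    rng = rng if rng is not None else cfg.rng()
    n_target = max(2, int(round(cfg.prop_genotyped * ped.n)))
    gen = generation_of(ped)
    order = np.argsort(-gen, kind="stable")  # latest generations first
    pool = order[: max(n_target, int((gen >= gen.max() - 1).sum()))]
    picked = rng.permutation(pool)[:n_target]
    return np.sort(picked)


def degrade(
    g: GenotypeMatrix,
    cfg: SimulationConfig,
    ped: Pedigree,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, DegradationRecord]:
    """Plant QC violations into a clean genotype matrix.

    Adds random missingness at ``cfg.missing_rate``, plus configurable
    numbers of monomorphic SNPs, low-call-rate SNPs, HWE-violating SNPs and
    opposing-homozygote conflict animals; returns the degraded matrix and
    an exact record of what was planted.
    """
    rng = rng if rng is not None else cfg.rng()
    dos = g.dosages.copy()
    mask = g.missing_mask.copy()
    rec = DegradationRecord()
    m, n = g.n_snps, g.n_animals
    ids = g.snp_map["id"].to_numpy()

    n_special = cfg.n_monomorphic + cfg.n_low_call + cfg.n_hwe_violations
    special = rng.choice(m, size=n_special, replace=False) if n_special else np.array([], int)
    mono = special[: cfg.n_monomorphic]
    lowc = special[cfg.n_monomorphic : cfg.n_monomorphic + cfg.n_low_call]
    hwe = special[cfg.n_monomorphic + cfg.n_low_call :]

    for j in mono:
        dos[:, j] = 0.0
        mask[:, j] = False
    rec.monomorphic_snps = [str(x) for x in ids[mono]]

    # fully called column with p=0.5 and no heterozygotes: maximal HWE violation
    for j in hwe:
        dos[:, j] = np.where(np.arange(n) % 2 == 0, 0.0, 2.0)
        mask[:, j] = False
    rec.hwe_snps = [str(x) for x in ids[hwe]]

    # conflict animals: genotyped parent available, no genotyped offspring
    if cfg.n_conflict_animals:
        pos = {a: i for i, a in enumerate(g.animal_ids)}
        has_geno_child = set()
        for a in g.animal_ids:
            if a in ped:
                c = ped.code(a)
                for p in (ped.sire[c], ped.dam[c]):
                    if p != UNKNOWN and ped.ids[p] in pos:
                        has_geno_child.add(ped.ids[p])
        candidates = []
        for a in g.animal_ids:
            if a in has_geno_child or a not in ped:
                continue
            c = ped.code(a)
            for p in (ped.sire[c], ped.dam[c]):
                if p != UNKNOWN and ped.ids[p] in pos:
                    candidates.append((a, ped.ids[p]))
                    break
        if len(candidates) < cfg.n_conflict_animals:
            raise ValueError("not enough genotyped parent-offspring pairs to plant conflicts")
        picks = rng.permutation(len(candidates))[: cfg.n_conflict_animals]
        for k in picks:
            child, parent = candidates[k]
            ci, pi = pos[child], pos[parent]
            hom = np.flatnonzero(
                ((dos[pi] == 0) | (dos[pi] == 2)) & ~mask[pi] & ~mask[ci]
                & ~np.isin(np.arange(m), special)
            )
            n_flip = max(1, int(np.ceil(cfg.conflict_rate * m)))
            if hom.size < n_flip:
                raise ValueError("too few homozygous parent sites to plant conflicts")
            sites = rng.choice(hom, size=n_flip, replace=False)
            dos[ci, sites] = 2.0 - dos[pi, sites]
            rec.conflict_animals.append(child)

    # random missingness on ordinary SNPs only, then the low-call columns
    if cfg.missing_rate > 0:
        ordinary = np.setdiff1d(np.arange(m), special)
        hit = rng.random((n, ordinary.size)) < cfg.missing_rate
        mask[:, ordinary] |= hit
    for j in lowc:
        miss = rng.random(n) < (1.0 - cfg.low_call_rate)
        need = int(np.ceil(n * (1.0 - cfg.low_call_rate + 0.05)))
        if miss.sum() < need:  # guarantee the call rate actually fails
            extra = rng.choice(np.flatnonzero(~miss), size=need - miss.sum(), replace=False)
            miss[extra] = True
        mask[:, j] = miss
    rec.low_call_snps = [str(x) for x in ids[lowc]]

    out = GenotypeMatrix(dos, mask, g.snp_map.copy(), list(g.animal_ids))
    return out, rec
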