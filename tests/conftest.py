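from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sswgwas.genotypes import GenotypeMatrix, allele_frequencies, center_matrix
from sswgwas.kinship import MarkerWeights, blend, g_matrix, h_inverse
from sswgwas.mme import ModelSpec, build_design, reml_aireml
from sswgwas.pedigree import Pedigree, a_inverse, a_submatrix, inbreeding
from sswgwas.synthetic import (SimulationConfig, assign_qtl, gene_drop,
                               sample_genotyped, simulate_pedigree,
                               simulate_phenotypes)


@pytest.fixture
def trio_ped() -> Pedigree:
    return Pedigree.from_records([("s", "0", "0"), ("d", "0", "0"), ("o", "s", "d")])


@pytest.fixture
def founders3() -> Pedigree:
    return Pedigree.from_records([(a, "0", "0") for a in "abc"])


def make_genotype_matrix(dosages, missing=None, chroms=None, positions=None,
                         animal_ids=None) -> GenotypeMatrix:
    dos = np.asarray(dosages, dtype=float)
    n, m = dos.shape
    return GenotypeMatrix(
        dosages=dos,
        missing_mask=(np.zeros_like(dos, dtype=bool)
                      if missing is None else np.asarray(missing, dtype=bool)),
        snp_map=pd.DataFrame({
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": positions if positions is not None else (np.arange(m) + 1) * 1000,
            "id": [f"snp{j}" for j in range(m)],
        }),
        animal_ids=(list(animal_ids) if animal_ids is not None
                    else [f"a{i}" for i in range(n)]),
    )


class SsDataset:
    """A simulated dataset plus the single-step machinery built on it."""

    def __init__(self, cfg: SimulationConfig, genotyped: str = "uniform"):
        rng = cfg.rng()
        self.cfg = cfg
        self.ped = simulate_pedigree(cfg, rng)
        self.g_all, self.founder_p = gene_drop(self.ped, cfg, rng)
        self.truth = assign_qtl(self.g_all, cfg, rng)
        self.phenotypes = simulate_phenotypes(self.truth, self.ped, cfg, rng)
        if genotyped == "uniform":
            n_t = max(2, int(round(cfg.prop_genotyped * self.ped.n)))
            self.genotyped = np.sort(rng.choice(self.ped.n, n_t, replace=False))
        else:
            self.genotyped = sample_genotyped(self.ped, cfg, rng)
        self.g = self.g_all.take_animals(self.genotyped)
        self.model = ModelSpec(trait="trait", factors=("period", "season"))
        self.design = build_design(self.phenotypes, self.model, self.ped)
        self.F = inbreeding(self.ped)
        self.Ainv = a_inverse(self.ped, self.F)
        self.A22 = a_submatrix(self.ped, self.genotyped)
        self.freqs = allele_frequencies(self.g)
        self.Z = center_matrix(self.g, self.freqs)
        self.weights = MarkerWeights.uniform(self.g.n_snps)
        self.G = g_matrix(self.Z, self.weights, self.freqs)
        self.Gstar = blend(self.G, self.A22, cfg_alpha(cfg))
        self.hinv = h_inverse(self.Ainv, self.A22, self.Gstar, self.genotyped,
                              cfg_alpha(cfg))

    def reml(self):
        d = self.design
        return reml_aireml(d.y, d.X, d.record_animals, self.hinv)


def cfg_alpha(cfg: SimulationConfig) -> float:
    return 0.95


@pytest.fixture(scope="session")
def medium_dataset() -> SsDataset:
    """Shared mid-size simulation for single-step tests (kept deterministic)."""
    cfg = SimulationConfig(
        n_founders=120, n_generations=6, n_sires=10, n_chromosomes=3,
        snps_per_chromosome=120, n_qtl=1, qtl_variance_fraction=0.2,
        h2=0.3, prop_genotyped=0.15, inter_snp_morgans=0.01, seed=42,
    )
    return SsDataset(cfg)
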